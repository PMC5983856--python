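"""Learning the nine voxel-class exemplars by affinity propagation.

The classifier at the heart of the pipeline is exemplar-based: 9x9 in-plane
HU patches (VOIs) are sampled from nodules of a training cohort, reduced to
first-order histogram features, compared by negative squared Euclidean
distance on standardized features, and clustered with affinity propagation
(AP). AP selects actual data points as cluster exemplars; the diagonal
"preference" of the similarity matrix controls how many emerge, and a
bisection on the preference calibrates the model to exactly nine classes.
The nine exemplars are then ranked by mean attenuation and labeled with the
color palette V, I, B, G, Y, O, R, C, P: the four most solid classes form
the invasion-associated VIRO group, the three most ground-glass classes the
lepidic group (B, C, G), with P and Y in between.

AP is implemented here directly (responsibility/availability message passing
with damping) so the preference path is fully under the calibration's
control.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .errors import CalibrationError, CapacityError
from .phantom import GroundTruth

#: The nine class labels, ordered by palette convention.
PALETTE: tuple[str, ...] = ("V", "I", "B", "G", "Y", "O", "R", "C", "P")
#: Invasion-associated (most solid) classes.
VIRO_CLASSES: frozenset[str] = frozenset({"V", "I", "R", "O"})
#: Lepidic-growth (ground-glass) classes.
LEPIDIC_CLASSES: frozenset[str] = frozenset({"B", "C", "G"})
#: Classes between lepidic and invasive.
INTERMEDIATE_CLASSES: frozenset[str] = frozenset({"P", "Y"})

#: In-plane window size: a classified voxel plus its 80 surrounding voxels.
WINDOW = 9
HALF_WINDOW = WINDOW // 2


@dataclass(frozen=True)
class VOIPatch:
    """A 9x9 in-plane HU patch centered on one nodule voxel."""

    values: np.ndarray  # (9, 9) float
    nodule_id: int
    center: tuple[int, int, int]

    def __post_init__(self) -> None:
        if np.asarray(self.values).shape != (WINDOW, WINDOW):
            raise ValueError(f"patch must be {WINDOW}x{WINDOW}")


@dataclass
class FeatureConfig:
    """First-order feature recipe for a VOI patch.

    A ``n_bins``-bin normalized histogram over ``[hu_min, hu_max]`` (values
    clamped to the range ends, half-open bins with the last bin closed),
    plus patch mean HU, HU standard deviation and histogram entropy (nats).
    """

    n_bins: int = 16
    hu_min: float = -1024.0
    hu_max: float = 200.0
    first_order: bool = True

    @property
    def n_features(self) -> int:
        return self.n_bins + (3 if self.first_order else 0)


def extract_features(patch: VOIPatch | np.ndarray,
                     config: FeatureConfig | None = None) -> np.ndarray:
    """Feature vector of one patch: histogram [+ mean, sd, entropy]."""
    config = config or FeatureConfig()
    values = patch.values if isinstance(patch, VOIPatch) else np.asarray(patch)
    return _features_batch(values.reshape(1, -1), config)[0]


def _features_batch(flat: np.ndarray, config: FeatureConfig) -> np.ndarray:
    """Vectorized feature extraction; ``flat`` is (n_patches, 81)."""
    n, m = flat.shape
    width = (config.hu_max - config.hu_min) / config.n_bins
    idx = np.floor((flat - config.hu_min) / width).astype(np.int64)
    np.clip(idx, 0, config.n_bins - 1, out=idx)  # clamps + closes the last bin
    hist = np.zeros((n, config.n_bins), dtype=np.float64)
    np.add.at(hist, (np.repeat(np.arange(n), m), idx.ravel()), 1.0)
    hist /= m
    if not config.first_order:
        return hist
    mean = flat.mean(axis=1)
    sd = flat.std(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(hist > 0, hist * np.log(hist), 0.0)
    entropy = -plogp.sum(axis=1)
    return np.column_stack([hist, mean, sd, entropy])


def sample_vois(cohort: Sequence[GroundTruth], n: int, seed: int = 0) -> list[VOIPatch]:
    """Sample ``n`` patches uniformly (without replacement) over all eligible
    centers in the cohort: nodule voxels whose 9x9 in-plane window lies
    fully inside the grid."""
    pool: list[tuple[int, int, int, int]] = []
    for nid, truth in enumerate(cohort):
        mask = truth.nodule_mask.values.astype(bool)
        _, nrow, ncol = mask.shape
        zs, ys, xs = np.nonzero(mask)
        ok = ((ys >= HALF_WINDOW) & (ys < nrow - HALF_WINDOW)
              & (xs >= HALF_WINDOW) & (xs < ncol - HALF_WINDOW))
        pool.extend(zip([nid] * int(ok.sum()), zs[ok], ys[ok], xs[ok]))
    if len(pool) < n:
        raise CapacityError(f"only {len(pool)} eligible VOI centers, need {n}")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pool), size=n, replace=False)
    patches = []
    for j in sorted(int(c) for c in chosen):
        nid, z, y, x = pool[j]
        vol = cohort[nid].volume.values
        patch = vol[z, y - HALF_WINDOW:y + HALF_WINDOW + 1,
                    x - HALF_WINDOW:x + HALF_WINDOW + 1]
        patches.append(VOIPatch(values=np.array(patch, dtype=float),
                                nodule_id=nid, center=(int(z), int(y), int(x))))
    return patches


def standardize(features: np.ndarray,
                mean: np.ndarray | None = None,
                sd: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-wise z-scoring; zero-variance columns map to 0."""
    X = np.asarray(features, dtype=float)
    if mean is None:
        mean = X.mean(axis=0)
    if sd is None:
        sd = X.std(axis=0)
    safe = np.where(sd > 0, sd, 1.0)
    Z = (X - mean) / safe
    Z[:, sd == 0] = 0.0
    return Z, mean, sd


@dataclass
class SimilarityMatrix:
    """Pairwise similarities s(i,k) with the preference on the diagonal."""

    matrix: np.ndarray
    preference: float

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def pairwise_similarity(features: np.ndarray,
                        preference: float | str = "median",
                        standardize_features: bool = True) -> SimilarityMatrix:
    """Similarity matrix s(i,k) = -||f_i - f_k||^2 (the canonical AP metric),
    optionally on column-standardized features; the diagonal is filled with
    the preference (``"median"`` = median off-diagonal similarity)."""
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D (n, d) array")
    if standardize_features:
        X, _, _ = standardize(X)
    n = X.shape[0]
    if n == 1:
        S = np.zeros((1, 1))
        pref = 0.0 if preference == "median" else float(preference)
        S[0, 0] = pref
        return SimilarityMatrix(matrix=S, preference=pref)
    S = -squareform(pdist(X, metric="sqeuclidean"))
    off = S[~np.eye(n, dtype=bool)]
    pref = float(np.median(off)) if preference == "median" else float(preference)
    np.fill_diagonal(S, pref)
    return SimilarityMatrix(matrix=S, preference=pref)


@dataclass
class APConfig:
    """Affinity-propagation message-passing controls."""

    damping: float = 0.9
    max_iterations: int = 1000
    convergence_window: int = 50

    def __post_init__(self) -> None:
        if not (0.5 <= self.damping < 1.0):
            raise ValueError("damping must be in [0.5, 1)")


@dataclass
class APResult:
    exemplars: np.ndarray      # indices of exemplar points, sorted
    assignment: np.ndarray     # assignment[i] = exemplar index of point i
    net_similarity: float      # sum_i s(i, e(i)), exemplars contribute s(k,k)
    converged: bool
    n_iterations: int

    @property
    def n_exemplars(self) -> int:
        return len(self.exemplars)


def _net_similarity(S: np.ndarray, exemplars: np.ndarray,
                    assignment: np.ndarray) -> float:
    return float(S[np.arange(S.shape[0]), assignment].sum())


def _assign(S: np.ndarray, exemplars: np.ndarray) -> np.ndarray:
    """Nearest-exemplar assignment; exemplars self-assigned; ties to lowest
    exemplar index (argmax picks the first maximum)."""
    sub = S[:, exemplars]
    assignment = exemplars[np.argmax(sub, axis=1)]
    assignment[exemplars] = exemplars
    return assignment


def _local_search(M: np.ndarray, exemplars: np.ndarray,
                  max_moves: int | None = None) -> np.ndarray:
    """Greedy add/drop polish of an exemplar set on the exact net-similarity
    objective (the quantity affinity propagation maximizes). Each move adds
    or removes one exemplar while the objective strictly improves."""
    # objective over an exemplar set E (facility-location form):
    #   sum_{i not in E} max_{e in E} s(i,e)  +  sum_{e in E} s(e,e)
    n = M.shape[0]
    p = M.diagonal().copy()
    E = np.zeros(n, dtype=bool)
    E[exemplars] = True
    max_moves = max_moves if max_moves is not None else 2 * n
    for _ in range(max_moves):
        idx = np.flatnonzero(E)
        k = len(idx)
        sub = M[:, idx].copy()
        sub[idx, np.arange(k)] = -np.inf  # an exemplar cannot serve itself here
        order = np.argsort(sub, axis=1)
        d1 = sub[np.arange(n), order[:, -1]]
        best_col = idx[order[:, -1]]
        d2 = sub[np.arange(n), order[:, -2]] if k > 1 else np.full(n, -np.inf)

        # adding candidate j: j switches from its current server to its own
        # preference; every other non-exemplar may switch to j
        gains_add = np.full(n, -np.inf)
        cand = np.flatnonzero(~E)
        if cand.size:
            improve = np.maximum(0.0, M[np.ix_(cand, cand)] - d1[cand][:, None])
            np.fill_diagonal(improve, 0.0)
            gains_add[cand] = p[cand] - d1[cand] + improve.sum(axis=0)

        # dropping exemplar e: its members fall back to their second-best
        # exemplar, and e itself becomes a served point
        gains_drop = np.full(n, -np.inf)
        if k > 1:
            for pos, e in enumerate(idx):
                members = (best_col == e) & ~E
                gains_drop[e] = (d2[members] - d1[members]).sum() + d1[e] - p[e]

        # swapping exemplar e out for candidate j (1-swap neighborhood);
        # scanned only while the k*n^2 work stays modest
        best_swap = (-np.inf, -1, -1)
        if k > 1 and cand.size and k * n * n <= 5e7:
            pc = p[cand]
            base_j = pc - d1[cand]  # j's own change when promoted
            for e in idx:
                served = (best_col == e) & ~E
                others = ~E & ~served
                t1 = (np.maximum(d2[served][:, None], M[np.ix_(served, cand)])
                      - d1[served][:, None]).sum(axis=0)
                t2 = np.maximum(0.0, M[np.ix_(others, cand)]
                                - d1[others][:, None]).sum(axis=0)
                # each candidate's own row term is wrong in t1/t2 (its true
                # change is base_j); subtract it, then add e's reassignment
                corr = np.where(served[cand],
                                -(np.maximum(d2[cand], pc) - d1[cand]),
                                -np.maximum(0.0, pc - d1[cand]))
                gains = (t1 + t2 + corr + base_j
                         + np.maximum(d1[e], M[e, cand]) - p[e])
                jj = int(np.argmax(gains))
                if gains[jj] > best_swap[0]:
                    best_swap = (float(gains[jj]), int(e), int(cand[jj]))

        j_add = int(np.argmax(gains_add))
        j_drop = int(np.argmax(gains_drop))
        moves = [(gains_add[j_add], ("add", j_add)),
                 (gains_drop[j_drop], ("drop", j_drop)),
                 (best_swap[0], ("swap", best_swap[1], best_swap[2]))]
        gain, move = max(moves, key=lambda m: m[0])
        if gain <= 1e-12:
            break
        if move[0] == "add":
            E[move[1]] = True
        elif move[0] == "drop":
            E[move[1]] = False
        else:
            E[move[1]] = False
            E[move[2]] = True
    return np.flatnonzero(E)


def affinity_propagation(S: SimilarityMatrix | np.ndarray,
                         config: APConfig | None = None) -> APResult:
    """Frey–Dueck affinity propagation with damped message passing.

    Runs until the exemplar set is unchanged for ``convergence_window``
    consecutive iterations or ``max_iterations`` is reached (flagged, with a
    warning, as non-converged). Deterministic given S and config.
    """
    config = config or APConfig()
    M = S.matrix if isinstance(S, SimilarityMatrix) else np.asarray(S, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("similarity matrix must be square")
    n = M.shape[0]
    if n == 1:
        return APResult(exemplars=np.array([0]), assignment=np.array([0]),
                        net_similarity=float(M[0, 0]), converged=True,
                        n_iterations=0)

    lam = config.damping
    R = np.zeros((n, n))
    A = np.zeros((n, n))
    ind = np.arange(n)
    last_E = None
    unchanged = 0
    converged = False
    it = 0
    for it in range(1, config.max_iterations + 1):
        # responsibilities: r(i,k) = s(i,k) - max_{k'!=k}[a(i,k') + s(i,k')]
        AS = A + M
        first_idx = np.argmax(AS, axis=1)
        first = AS[ind, first_idx]
        AS[ind, first_idx] = -np.inf
        second = AS.max(axis=1)
        AS[ind, first_idx] = first
        Rnew = M - first[:, None]
        Rnew[ind, first_idx] = M[ind, first_idx] - second
        R = lam * R + (1 - lam) * Rnew

        # availabilities: a(i,k) = min(0, r(k,k) + sum_{i' not in {i,k}} max(0, r(i',k)))
        #                 a(k,k) = sum_{i'!=k} max(0, r(i',k))
        Rp = np.maximum(R, 0)
        Rp[ind, ind] = R[ind, ind]
        colsum = Rp.sum(axis=0)
        Anew = np.minimum(0, colsum[None, :] - Rp)
        Anew[ind, ind] = colsum - R[ind, ind]
        A = lam * A + (1 - lam) * Anew

        E = (A + R).diagonal() > 0
        if last_E is not None and np.array_equal(E, last_E) and E.any():
            unchanged += 1
            if unchanged >= config.convergence_window:
                converged = True
                break
        else:
            unchanged = 0
        last_E = E.copy()

    E = (A + R).diagonal() > 0
    if not E.any():  # degenerate: fall back to the single best candidate
        E[int(np.argmax((A + R).diagonal()))] = True
    exemplars = np.flatnonzero(E)
    # polish the message-passing solution on the exact objective: cluster-wise
    # exemplar re-selection (the canonical refinement pass) alternating with a
    # greedy add/drop local search, until the set is stable
    assignment = _assign(M, exemplars)
    for _ in range(n):
        refined = []
        for ex in exemplars:
            members = np.flatnonzero(assignment == ex)
            scores = M[np.ix_(members, members)].sum(axis=0)
            refined.append(int(members[int(np.argmax(scores))]))
        refined = _local_search(M, np.unique(refined))
        if np.array_equal(refined, exemplars):
            break
        exemplars = refined
        assignment = _assign(M, exemplars)
    if not converged:
        warnings.warn(f"affinity propagation did not converge within "
                      f"{config.max_iterations} iterations", RuntimeWarning)
    return APResult(exemplars=exemplars, assignment=assignment,
                    net_similarity=_net_similarity(M, exemplars, assignment),
                    converged=converged, n_iterations=it)


def calibrate_preference(S: SimilarityMatrix, target_k: int = 9,
                         config: APConfig | None = None,
                         max_bisections: int = 60) -> tuple[float, APResult]:
    """Bisect the diagonal preference until AP yields exactly ``target_k``
    exemplars.

    The exemplar count is (in practice) non-decreasing in the preference, so
    a bisection between the minimum similarity and the maximum off-diagonal
    similarity brackets every attainable count. Raises
    :class:`CalibrationError`, reporting the nearest achievable counts, if
    ``target_k`` is never hit.
    """
    config = config or APConfig()
    M = S.matrix.copy()
    n = M.shape[0]
    if target_k > n:
        raise CalibrationError(f"target_k={target_k} exceeds n={n}")
    off = M[~np.eye(n, dtype=bool)]

    def run(pref: float) -> APResult:
        np.fill_diagonal(M, pref)
        return affinity_propagation(SimilarityMatrix(matrix=M, preference=pref),
                                    config)

    lo, hi = float(off.min()), float(off.max())
    res_lo = run(lo)
    # expand downward if even the minimum similarity yields too many classes
    tries = 0
    while res_lo.n_exemplars > target_k and tries < 6:
        lo *= 4.0
        res_lo = run(lo)
        tries += 1
    if res_lo.n_exemplars == target_k:
        return lo, res_lo
    res_hi = run(hi)
    # expand upward toward zero preference if even the maximum off-diagonal
    # similarity yields too few exemplars (e.g. target_k == n)
    tries = 0
    while res_hi.n_exemplars < target_k and hi < -1e-12 and tries < 6:
        hi /= 4.0
        if hi > -1e-12:
            hi = 0.0
        res_hi = run(hi)
        tries += 1
    if res_hi.n_exemplars == target_k:
        return hi, res_hi
    if res_lo.n_exemplars > target_k or res_hi.n_exemplars < target_k:
        raise CalibrationError(
            f"exemplar count range [{res_lo.n_exemplars}, {res_hi.n_exemplars}] "
            f"does not bracket target {target_k}",
            nearest_below=res_lo.n_exemplars, nearest_above=res_hi.n_exemplars)

    below, above = res_lo.n_exemplars, res_hi.n_exemplars
    for _ in range(max_bisections):
        mid = 0.5 * (lo + hi)
        res = run(mid)
        k = res.n_exemplars
        if k == target_k:
            return mid, res
        if k < target_k:
            lo, below = mid, max(below, k)
        else:
            hi, above = mid, min(above, k)
    raise CalibrationError(
        f"bisection exhausted without hitting {target_k} exemplars "
        f"(nearest counts: {below} below, {above} above)",
        nearest_below=below, nearest_above=above)


@dataclass
class ExemplarModel:
    """Nine labeled exemplars plus everything needed to classify new voxels.

    ``features_raw`` are the exemplars' unstandardized feature vectors;
    ``feat_mean``/``feat_sd`` are the training-set standardization applied
    before distance computations; ``labels[i]`` is the palette class of
    exemplar ``i``.
    """

    features_raw: np.ndarray
    feat_mean: np.ndarray
    feat_sd: np.ndarray
    labels: list[str]
    mean_hu: np.ndarray
    config: FeatureConfig
    preference: float = 0.0
    manifest: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.features_raw = np.asarray(self.features_raw, dtype=float)

    @property
    def n_classes(self) -> int:
        return self.features_raw.shape[0]

    @property
    def features_std(self) -> np.ndarray:
        Z, _, _ = standardize(self.features_raw, self.feat_mean, self.feat_sd)
        return Z

    def to_json(self, path: str | Path | None = None) -> str:
        d = {
            "features_raw": self.features_raw.tolist(),
            "feat_mean": np.asarray(self.feat_mean).tolist(),
            "feat_sd": np.asarray(self.feat_sd).tolist(),
            "labels": list(self.labels),
            "mean_hu": np.asarray(self.mean_hu).tolist(),
            "config": asdict(self.config),
            "preference": self.preference,
            "manifest": self.manifest,
        }
        text = json.dumps(d, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ExemplarModel":
        s = str(source)
        text = s if s.lstrip().startswith("{") else Path(source).read_text()
        d = json.loads(text)
        return cls(features_raw=np.asarray(d["features_raw"]),
                   feat_mean=np.asarray(d["feat_mean"]),
                   feat_sd=np.asarray(d["feat_sd"]),
                   labels=list(d["labels"]),
                   mean_hu=np.asarray(d["mean_hu"]),
                   config=FeatureConfig(**d["config"]),
                   preference=float(d["preference"]),
                   manifest=d.get("manifest", {}))


def label_classes(mean_hu: np.ndarray) -> list[str]:
    """Assign the palette to nine exemplars ranked by mean attenuation.

    Ascending mean HU: the three most ground-glass exemplars get G, C, B;
    the middle two get P, Y; the four most solid get (descending) R, O, V, I.
    Frozen sub-order within each block.
    """
    mean_hu = np.asarray(mean_hu, dtype=float)
    if mean_hu.shape[0] != 9:
        raise ValueError(f"expected 9 exemplars, got {mean_hu.shape[0]}")
    order = np.argsort(mean_hu, kind="stable")  # ascending attenuation
    by_rank = ["G", "C", "B", "P", "Y", "I", "V", "O", "R"]
    labels = [""] * 9
    for rank, ex in enumerate(order):
        labels[int(ex)] = by_rank[rank]
    return labels


def train_exemplar_model(cohort: Sequence[GroundTruth], n_vois: int = 774,
                         target_k: int = 9, seed: int = 0,
                         feature_config: FeatureConfig | None = None,
                         ap_config: APConfig | None = None) -> ExemplarModel:
    """End-to-end training: sample VOIs, extract features, calibrate AP to
    ``target_k`` exemplars, label classes along the attenuation spectrum."""
    feature_config = feature_config or FeatureConfig()
    patches = sample_vois(cohort, n_vois, seed=seed)
    flat = np.stack([p.values.ravel() for p in patches])
    X = _features_batch(flat, feature_config)
    Z, mu, sd = standardize(X)
    S = pairwise_similarity(Z, preference="median", standardize_features=False)
    pref, result = calibrate_preference(S, target_k=target_k, config=ap_config)
    ex = result.exemplars
    mean_hu = flat[ex].mean(axis=1)
    labels = label_classes(mean_hu) if target_k == 9 else [str(i) for i in range(len(ex))]
    manifest = {
        "n_vois": n_vois,
        "n_nodules": len(cohort),
        "seed": seed,
        "target_k": target_k,
        "preference": pref,
        "converged": bool(result.converged),
        "exemplar_centers": [list(map(int, patches[i].center)) for i in ex],
        "exemplar_nodules": [int(patches[i].nodule_id) for i in ex],
    }
    return ExemplarModel(features_raw=X[ex], feat_mean=mu, feat_sd=sd,
                         labels=labels, mean_hu=mean_hu, config=feature_config,
                         preference=pref, manifest=manifest)
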