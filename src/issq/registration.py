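"""Pairwise tile registration: the overlap constraint graph.

Every pair of tiles whose nominal positions imply shared content — within a
cycle or between cycles — contributes a *constraint*: a pairwise
translational offset with a confidence score.  Constraints start from the
nominal stage positions, are refined by FFT-based circular
cross-correlation with ZNCC disambiguation of the wrap-around ambiguity,
are filtered against a null distribution of scores from non-overlapping
tile pairs, and the filtered ones are replaced by predictions of a robust
linear stage model fitted on the surviving constraints.

Offset convention: for a constraint on pair ``(i, j)``,
``(dx, dy) = position(j) - position(i)``.  An offset ``(dx, dy)`` places
pixel ``(0, 0)`` of tile ``j`` at coordinates ``(dx, dy)`` of tile ``i``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LinearRegression, RANSACRegressor

from .tiles import TileCollection

__all__ = [
    "Constraint",
    "ConstraintGraph",
    "StageModel",
    "zncc",
    "phase_align",
    "build_adjacency_graph",
    "estimate_score_threshold",
    "filter_constraints",
    "fit_stage_model",
    "impute_constraints",
    "register_tiles",
]

#: Imputed constraints never carry a weight below this floor.
MIN_WEIGHT = 0.05


@dataclass
class Constraint:
    """Pairwise positional constraint between tiles ``i`` and ``j``."""

    i: int
    j: int
    dx: float
    dy: float
    dx_refined: float | None = None
    dy_refined: float | None = None
    score: float | None = None
    status: str = "initial"  # initial | measured | filtered | imputed | failed
    tie: bool = False

    @property
    def initial_offset(self) -> tuple[float, float]:
        return self.dx, self.dy

    @property
    def refined_offset(self) -> tuple[float, float]:
        if self.dx_refined is None:
            raise ValueError("constraint not refined")
        return self.dx_refined, self.dy_refined

    def weight(self, floor: float) -> float:
        """Score weight used in the global solve (floored for imputed edges)."""
        if self.status == "imputed":
            return floor
        return max(float(self.score), floor)


@dataclass
class ConstraintGraph:
    """All pairwise constraints over a tile collection."""

    tiles: TileCollection
    constraints: list[Constraint] = field(default_factory=list)
    s_thresh: float | None = None
    null_samples: list[tuple[int, int, float]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.constraints)

    @property
    def node_ids(self) -> list[int]:
        return sorted(t.id for t in self.tiles)

    @property
    def active(self) -> list[Constraint]:
        """Constraints that participate in the global solve."""
        return [c for c in self.constraints if c.status in ("measured", "imputed")]

    @property
    def weight_floor(self) -> float:
        thresh = self.s_thresh if self.s_thresh is not None else MIN_WEIGHT
        return max(thresh, MIN_WEIGHT)


def zncc(raster_a: np.ndarray, raster_b: np.ndarray, offset: tuple[float, float]) -> float:
    """Zero-normalised cross-correlation of the overlap implied by ``offset``.

    Both overlap vectors are mean-centred and scaled to unit norm; the score
    is their dot product, in [-1, 1].  A zero-variance overlap is
    uninformative and scores 0 (with a warning); an overlap of fewer than
    2 pixels scores ``-inf`` so callers can discard the candidate.
    """
    a = np.asarray(raster_a, dtype=float)
    b = np.asarray(raster_b, dtype=float)
    dx, dy = int(round(offset[0])), int(round(offset[1]))
    ha, wa = a.shape
    hb, wb = b.shape
    x0, x1 = max(0, dx), min(wa, dx + wb)
    y0, y1 = max(0, dy), min(ha, dy + hb)
    if x1 - x0 < 1 or y1 - y0 < 1 or (x1 - x0) * (y1 - y0) < 2:
        return float("-inf")
    va = a[y0:y1, x0:x1].ravel()
    vb = b[y0 - dy : y1 - dy, x0 - dx : x1 - dx].ravel()
    va = va - va.mean()
    vb = vb - vb.mean()
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        warnings.warn("zero-variance overlap; ZNCC undefined, scoring 0")
        return 0.0
    return float(np.clip(va @ vb / (na * nb), -1.0, 1.0))


def _cross_power_surface(
    a: np.ndarray, b: np.ndarray, normalization: str = "none"
) -> np.ndarray:
    """Circular cross-correlation surface of two rasters, via FFT.

    The inverse FFT of the cross-power spectrum peaks at the translation of
    ``b`` relative to ``a``.  Both rasters are mean-removed first, which
    keeps the plain correlation (the default) from favouring high-energy
    overlaps regardless of content.  ``normalization='phase'`` whitens the
    spectrum (classic phase correlation): sharper peaks on feature-rich
    images, but unreliable on smooth textures whose high frequencies are
    pure noise.  Rasters of unequal shape are zero-padded to a common
    shape.
    """
    ha, wa = a.shape
    hb, wb = b.shape
    H, W = max(ha, hb), max(wa, wb)
    pa = np.zeros((H, W))
    pb = np.zeros((H, W))
    pa[:ha, :wa] = a - a.mean()
    pb[:hb, :wb] = b - b.mean()
    fa = np.fft.fft2(pa)
    fb = np.fft.fft2(pb)
    cross = fa * np.conj(fb)
    if normalization == "phase":
        mag = np.abs(cross)
        mag[mag == 0] = 1.0
        cross = cross / mag
    elif normalization != "none":
        raise ValueError(f"unknown normalization {normalization!r}")
    return np.real(np.fft.ifft2(cross))


def phase_align(
    raster_a: np.ndarray,
    raster_b: np.ndarray,
    constraint: Constraint,
    n_peaks: int = 2,
    min_overlap_frac: float = 0.01,
    normalization: str = "none",
) -> Constraint:
    """Refine a constraint by circular cross-correlation + ZNCC scoring.

    The correlation surface is circular, so each maximum corresponds to
    four possible true offsets (wrap-around in x, in y, in both, or
    neither).  The top ``n_peaks`` maxima are expanded into their four
    candidates each, every candidate is scored by ZNCC on the overlap it
    implies, and the best-scoring candidate wins.  Candidates whose overlap
    is empty or covers less than ``min_overlap_frac`` of the smaller tile
    are discarded; if all candidates are discarded the constraint is marked
    ``failed`` with score -1.
    """
    a = np.asarray(raster_a, dtype=float)
    b = np.asarray(raster_b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        constraint.status = "failed"
        constraint.score = -1.0
        constraint.dx_refined, constraint.dy_refined = constraint.dx, constraint.dy
        return constraint
    surface = _cross_power_surface(a, b, normalization=normalization)
    H, W = surface.shape
    flat = np.argsort(surface.ravel())[::-1][:n_peaks]
    min_area = max(2, int(min_overlap_frac * min(a.size, b.size)))

    best: tuple[float, int, int] | None = None
    for idx in flat:
        py, px = divmod(int(idx), W)
        for dy in (py, py - H):
            for dx in (px, px - W):
                s = zncc(a, b, (dx, dy))
                if not np.isfinite(s):
                    continue
                x0, x1 = max(0, dx), min(a.shape[1], dx + b.shape[1])
                y0, y1 = max(0, dy), min(a.shape[0], dy + b.shape[0])
                if (x1 - x0) * (y1 - y0) < min_area:
                    continue
                # strict > keeps the first candidate in scan order on ties
                if best is None or s > best[0]:
                    best = (s, dx, dy)
    if best is None:
        constraint.status = "failed"
        constraint.score = -1.0
        constraint.dx_refined, constraint.dy_refined = constraint.dx, constraint.dy
        return constraint
    s, dx, dy = best
    constraint.dx_refined, constraint.dy_refined = float(dx), float(dy)
    constraint.score = s
    constraint.status = "measured"
    return constraint


def build_adjacency_graph(tiles: TileCollection) -> ConstraintGraph:
    """Build one constraint per unordered pair of overlapping tiles.

    A pair ``(i, j)`` with nominal offset ``(dx, dy) = pos_j - pos_i``
    overlaps when ``-w_j <= dx <= w_i`` and ``-h_j <= dy <= h_i``.  Pairs
    from the same cycle and from different cycles are treated alike.
    """
    if len(tiles) == 0:
        raise ValueError("empty tile collection")
    graph = ConstraintGraph(tiles)
    tile_list = sorted(tiles, key=lambda t: t.id)
    for a_idx in range(len(tile_list)):
        ti = tile_list[a_idx]
        wi, hi = ti.size
        for b_idx in range(a_idx + 1, len(tile_list)):
            tj = tile_list[b_idx]
            wj, hj = tj.size
            dx, dy = tj.position - ti.position
            if -wj <= dx <= wi and -hj <= dy <= hi:
                graph.constraints.append(Constraint(ti.id, tj.id, float(dx), float(dy)))
    return graph


def refine_graph(graph: ConstraintGraph) -> ConstraintGraph:
    """Run :func:`phase_align` on every constraint of the graph."""
    tiles = graph.tiles
    rasters = {t.id: tiles.fiducial(t) for t in tiles}
    for c in graph.constraints:
        phase_align(rasters[c.i], rasters[c.j], c)
    return graph


def _scrambled_offset_score(
    a: np.ndarray, b: np.ndarray, rng: np.random.Generator, n_offsets: int = 8
) -> float:
    """Best ZNCC over random wrong offsets — a null score for a pair whose
    content does overlap.  Offsets keep at least half a tile of
    displacement in one axis so the true alignment cannot be sampled."""
    h, w = a.shape
    best = -1.0
    for _ in range(n_offsets):
        dx = int(rng.integers(w // 2, max(w - 4, w // 2 + 1)))
        dy = int(rng.integers(-h // 2, h // 2 + 1))
        if rng.random() < 0.5:
            dx, dy = dy, abs(dx)
        s = zncc(a, b, (dx, dy))
        if np.isfinite(s):
            best = max(best, s)
    return best


def nearest_rank_percentile(scores, percentile: float) -> float:
    """Nearest-rank percentile: the smallest sample value with at least
    ``percentile`` percent of the sample at or below it (no interpolation)."""
    ordered = sorted(scores)
    k = int(np.ceil(percentile / 100.0 * len(ordered)))
    return float(ordered[max(k - 1, 0)])


def estimate_score_threshold(
    tiles: TileCollection,
    n_pairs: int = 100,
    percentile: float = 95.0,
    rng_seed: int = 0,
    record: ConstraintGraph | None = None,
) -> float:
    """Null ZNCC score threshold from distant (non-overlapping) tile pairs.

    Samples up to ``n_pairs`` pairs whose nominal separation exceeds twice
    the larger tile dimension in *both* x and y, aligns each with
    :func:`phase_align`, and returns the ``percentile``-th score by the
    nearest-rank rule.  When too few pairs meet the distance criterion the
    sample is topped up from merely non-overlapping pairs (and, as a last
    resort for very small collections, any pairs), with a warning.
    """
    tile_list = sorted(tiles, key=lambda t: t.id)
    if len(tile_list) < 2:
        raise ValueError("need at least 2 tiles to estimate a null score")
    distant: list[tuple[int, int]] = []
    nonoverlap: list[tuple[int, int]] = []
    others: list[tuple[int, int]] = []
    for a in range(len(tile_list)):
        ti = tile_list[a]
        wi, hi = ti.size
        for b in range(a + 1, len(tile_list)):
            tj = tile_list[b]
            wj, hj = tj.size
            dx, dy = tj.position - ti.position
            pair = (ti.id, tj.id)
            if abs(dx) > 2 * max(wi, wj) and abs(dy) > 2 * max(hi, hj):
                distant.append(pair)
            elif not (-wj <= dx <= wi and -hj <= dy <= hi):
                nonoverlap.append(pair)
            else:
                others.append(pair)

    rng = np.random.default_rng(rng_seed)
    pool = [(i, j, False) for i, j in distant]
    if len(pool) < n_pairs:
        warnings.warn(
            f"only {len(pool)} tile pairs meet the 2x-dimension distance "
            "criterion; relaxing to non-overlapping pairs"
        )
        extra = [(i, j, False) for i, j in nonoverlap]
        if not extra:
            # very small collections: every pair truly overlaps, so the null
            # is taken from overlapping pairs scored at deliberately wrong
            # offsets (their aligned score would be no null at all)
            extra = [(i, j, True) for i, j in others]
        rng.shuffle(extra)
        pool += extra[: n_pairs - len(pool)]
    if len(pool) > n_pairs:
        idx = rng.choice(len(pool), size=n_pairs, replace=False)
        pool = [pool[k] for k in sorted(idx)]

    rasters = {t.id: tiles.fiducial(t) for t in tiles}
    scores: list[float] = []
    samples: list[tuple[int, int, float]] = []
    for i, j, scrambled in pool:
        if scrambled:
            s = _scrambled_offset_score(rasters[i], rasters[j], rng)
        else:
            c = Constraint(i, j, 0.0, 0.0)
            phase_align(rasters[i], rasters[j], c)
            s = c.score
        scores.append(s)
        samples.append((i, j, s))
    s_thresh = nearest_rank_percentile(scores, percentile)
    if record is not None:
        record.null_samples = samples
        record.s_thresh = s_thresh
    return s_thresh


def filter_constraints(graph: ConstraintGraph, s_thresh: float | None = None) -> ConstraintGraph:
    """Demote constraints scoring below the null threshold to ``filtered``."""
    if s_thresh is None:
        s_thresh = graph.s_thresh
    if s_thresh is None:
        raise ValueError("no score threshold available")
    graph.s_thresh = float(s_thresh)
    for c in graph.constraints:
        if c.status in ("measured", "failed") and c.score < s_thresh:
            c.status = "filtered"
    if not any(c.status == "measured" for c in graph.constraints):
        raise ValueError("every constraint fell below the score threshold")
    return graph


@dataclass
class StageModel:
    """Linear map from initial (nominal) offsets to refined offsets.

    Captures systematic stage behaviour — the actual travel between grid
    positions and any camera/stage axis misalignment — as a 2x2 matrix plus
    intercept, fitted jointly on x and y with an outlier-robust regressor.
    """

    coef: np.ndarray  # (2, 2)
    intercept: np.ndarray  # (2,)
    inlier_mask: np.ndarray | None = None

    def predict(self, offsets: np.ndarray) -> np.ndarray:
        offsets = np.atleast_2d(np.asarray(offsets, dtype=float))
        return offsets @ self.coef.T + self.intercept

    @classmethod
    def identity(cls) -> "StageModel":
        return cls(np.eye(2), np.zeros(2))


def fit_stage_model(
    constraints: list[Constraint],
    residual_threshold: float = 10.0,
    rng_seed: int = 0,
    demote_outliers: bool = True,
) -> StageModel:
    """Fit the stage model on measured, score-passing constraints by RANSAC.

    Residual outliers (gross mis-registrations that slipped past the score
    filter) are demoted to ``filtered`` status so they too get imputed.
    ``residual_threshold`` separates legitimate stage jitter — a few pixels
    on either tile of a pair — from misregistrations, which are off by tens
    of pixels or more; 10 px sits between the two regimes.
    Falls back to the identity map, with a warning, when the design is
    rank-deficient (fewer than 3 constraints or collinear offsets).
    """
    fit_set = [c for c in constraints if c.status == "measured"]
    X = np.array([[c.dx, c.dy] for c in fit_set], dtype=float).reshape(-1, 2)
    Y = np.array(
        [[c.dx_refined, c.dy_refined] for c in fit_set], dtype=float
    ).reshape(-1, 2)
    if len(fit_set) < 3 or np.linalg.matrix_rank(np.column_stack([X, np.ones(len(X))])) < 3:
        warnings.warn("rank-deficient constraint design; stage model set to identity")
        return StageModel.identity()
    try:
        ransac = RANSACRegressor(
            LinearRegression(),
            residual_threshold=residual_threshold,
            random_state=rng_seed,
        )
        ransac.fit(X, Y)
        est = ransac.estimator_
        inliers = ransac.inlier_mask_
        coef = np.asarray(est.coef_, dtype=float)
        intercept = np.asarray(est.intercept_, dtype=float)
    except ValueError:
        warnings.warn("RANSAC failed to find a consensus; stage model set to identity")
        return StageModel.identity()
    if demote_outliers:
        for c, ok in zip(fit_set, inliers):
            if not ok:
                c.status = "filtered"
    return StageModel(coef, intercept, inlier_mask=inliers)


def impute_constraints(graph: ConstraintGraph, model: StageModel) -> ConstraintGraph:
    """Replace filtered/failed constraints with stage-model predictions.

    The edge set never changes: each filtered constraint keeps its
    endpoints and receives the model-predicted offset, ``imputed`` status
    and the graph's floor weight in the global solve.
    """
    for c in graph.constraints:
        if c.status in ("filtered", "failed"):
            pred = model.predict([c.initial_offset])[0]
            c.dx_refined, c.dy_refined = float(pred[0]), float(pred[1])
            c.status = "imputed"
    return graph


def register_tiles(
    tiles: TileCollection,
    n_null_pairs: int = 100,
    percentile: float = 95.0,
    rng_seed: int = 0,
) -> ConstraintGraph:
    """Full registration pass: graph, refinement, filtering, imputation."""
    graph = build_adjacency_graph(tiles)
    refine_graph(graph)
    estimate_score_threshold(
        tiles, n_pairs=n_null_pairs, percentile=percentile, rng_seed=rng_seed,
        record=graph,
    )
    filter_constraints(graph)
    model = fit_stage_model(graph.constraints, rng_seed=rng_seed)
    impute_constraints(graph, model)
    return graph
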