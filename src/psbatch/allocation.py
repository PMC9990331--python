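"""Sample-to-batch allocation strategies for balanced case-control designs.

The optimal strategy screens candidate within-stratum blocks by propensity
score: for every possible block of subjects, a logistic regression of block
membership on the covariates yields fitted membership probabilities, and the
absolute difference between the mean fitted probability inside and outside
the block measures how distinguishable the block is from the rest of the
stratum (zero gap = perfect covariate balance). The lowest-gap disjoint
blocks per stratum are then paired across strata into batches, with pairs
ranked jointly on between-batch and within-batch (case vs control) gaps.

Randomized comparators (simple, stratified, best-of-R constrained
randomization) are provided with explicit seeding.

All tie-breaks are lexicographic on subject-id membership, so every
allocator is deterministic given its inputs (and seed, where one exists).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Sequence, TypeVar

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import rankdata

from .cohort import CASE, CONTROL, Cohort

__all__ = [
    "EnumerationCapError",
    "PropensityFit",
    "BlockScore",
    "BatchCombo",
    "BatchAssignment",
    "fit_logistic_ps",
    "ps_gap",
    "enumerate_blocks",
    "score_blocks",
    "select_disjoint",
    "score_batch_combos",
    "optimal_allocate",
    "random_allocate",
    "stratified_allocate",
    "constrained_random_allocate",
]

DEFAULT_CAP = 10**6
RIDGE = 1e-6
MAX_ITER = 25
TOL = 1e-8


class EnumerationCapError(ValueError):
    """Block enumeration would exceed the configured cap."""


# ---------------------------------------------------------------------------
# Logistic propensity-score fitting (batched IRLS)
# ---------------------------------------------------------------------------


def _penalized_nll(beta: np.ndarray, X: np.ndarray, Y: np.ndarray,
                   pen_vec: np.ndarray) -> np.ndarray:
    """Per-row penalized negative log-likelihood (stable in eta)."""
    eta = beta @ X.T
    ll = (Y * eta - np.logaddexp(0.0, eta)).sum(axis=1)
    return -ll + 0.5 * (pen_vec * beta**2).sum(axis=1)


def _irls(X: np.ndarray, Y: np.ndarray, *, ridge: float = 0.0,
          max_iter: int = MAX_ITER, tol: float = TOL) -> tuple[np.ndarray, np.ndarray]:
    """Batched iteratively reweighted least squares for logistic regression.

    Fits one logistic model per row of ``Y`` (shape B x n, values 0/1), all
    sharing the design ``X`` (shape n x p, intercept in column 0). ``ridge``
    penalizes the non-intercept coefficients. Newton/IRLS steps are
    step-halved whenever they fail to improve the penalized likelihood, so
    separable indicators (common for small blocks in two covariates) stay
    finite: their fitted probabilities saturate towards the indicator and
    the row is flagged unconverged instead of overflowing.

    Returns ``(beta, converged)`` with ``beta`` of shape (B, p).
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    B, n = Y.shape
    p = X.shape[1]
    beta = np.zeros((B, p))
    converged = np.zeros(B, dtype=bool)
    pen_vec = np.zeros(p)
    pen_vec[1:] = ridge
    pen = np.diag(pen_vec)

    active = np.arange(B)
    nll = _penalized_nll(beta, X, Y, pen_vec)
    for _ in range(max_iter):
        if active.size == 0:
            break
        cur = beta[active]
        eta = cur @ X.T
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (Y[active] - mu) / w
        A = np.einsum("bn,ni,nj->bij", w, X, X, optimize=True) + pen
        rhs = np.einsum("bn,ni->bi", w * z, X)
        try:
            prop = np.linalg.solve(A, rhs[..., None])[..., 0]
        except np.linalg.LinAlgError:
            # Rank-deficient working matrix: tiny jitter keeps the batch solvable.
            A = A + 1e-10 * np.eye(p)
            prop = np.linalg.solve(A, rhs[..., None])[..., 0]
        prop = np.where(np.isfinite(prop), prop, cur)

        # Backtracking: halve any step that worsens the penalized likelihood.
        new = prop
        new_nll = _penalized_nll(new, X, Y[active], pen_vec)
        for _halve in range(30):
            worse = ~(new_nll <= nll[active] + 1e-12)
            if not worse.any():
                break
            new = new.copy()
            new[worse] = 0.5 * (new[worse] + cur[worse])
            new_nll[worse] = _penalized_nll(new[worse], X, Y[active][worse], pen_vec)
        else:
            new = np.where((new_nll <= nll[active] + 1e-12)[:, None], new, cur)
            new_nll = np.minimum(new_nll, nll[active])

        delta = np.abs(new - cur).max(axis=1)
        beta[active] = new
        nll[active] = new_nll
        done = delta < tol
        converged[active[done]] = True
        active = active[~done]
    return beta, converged


def _fit_many(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fit logistic models for each indicator row; ridge fallback on failure.

    Separation is common when a block of a handful of subjects is regressed
    on two covariates; any row that has not converged after the plain IRLS
    pass is refit with a small ridge penalty on the slopes.

    Returns ``(beta, prob, converged, ridge_used)``.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    rank_deficient = np.linalg.matrix_rank(X) < X.shape[1]
    if rank_deficient:
        beta, conv = _irls(X, Y, ridge=RIDGE)
        ridge_used = np.ones(Y.shape[0], dtype=bool)
    else:
        beta, conv = _irls(X, Y)
        ridge_used = np.zeros(Y.shape[0], dtype=bool)
        if not conv.all():
            retry = ~conv
            beta_r, conv_r = _irls(X, Y[retry], ridge=RIDGE)
            beta[retry] = beta_r
            conv[retry] = conv_r
            ridge_used = retry
    prob = expit(beta @ X.T)
    return beta, prob, conv, ridge_used


def _design(covariates: pd.DataFrame | np.ndarray) -> np.ndarray:
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if not np.all(np.isfinite(C)):
        raise ValueError("covariates must be finite")
    return np.column_stack([np.ones(len(C)), C])


@dataclass
class PropensityFit:
    """A fitted logistic propensity-score model.

    ``coefficients`` holds intercept + one slope per covariate (log-odds);
    ``fitted_prob`` maps each subject to its fitted membership probability.
    """

    coefficients: np.ndarray
    fitted_prob: pd.Series
    converged: bool
    ridge_used: bool


def fit_logistic_ps(covariates: pd.DataFrame, indicator) -> PropensityFit:
    """Maximum-likelihood logistic fit of a 0/1 indicator on covariates.

    Solved by IRLS (max 25 iterations, tol 1e-8 on the max coefficient
    change); on non-convergence or a rank-deficient design, refit with a
    ridge penalty of 1e-6 on the slopes and flag ``ridge_used``.
    """
    y = np.asarray(indicator, dtype=float)
    if y.ndim != 1 or len(y) != len(covariates):
        raise ValueError("indicator must align with covariate rows")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("indicator must be 0/1")
    if y.min() == y.max():
        raise ValueError("indicator must contain both classes")
    X = _design(covariates)
    beta, prob, conv, ridge_used = _fit_many(X, y[None, :])
    index = covariates.index if isinstance(covariates, pd.DataFrame) else pd.RangeIndex(len(y))
    return PropensityFit(
        coefficients=beta[0],
        fitted_prob=pd.Series(prob[0], index=index),
        converged=bool(conv[0]),
        ridge_used=bool(ridge_used[0]),
    )


def ps_gap(fitted_prob, indicator) -> float:
    """Absolute difference in mean propensity score between the two classes."""
    p = np.asarray(fitted_prob, dtype=float)
    y = np.asarray(indicator, dtype=float)
    if p.shape != y.shape:
        raise ValueError("fitted_prob and indicator must have the same length")
    inside = y == 1
    if inside.all() or (~inside).all():
        raise ValueError("indicator must contain both classes")
    return float(abs(p[inside].mean() - p[~inside].mean()))


# ---------------------------------------------------------------------------
# Block enumeration and scoring
# ---------------------------------------------------------------------------


def enumerate_blocks(ids: Sequence, block_size: int) -> Iterator[tuple]:
    """Lazily yield every size-``block_size`` subset of ``ids``.

    Lexicographic in the order of ``ids``; total count C(|ids|, block_size).
    """
    if block_size <= 0:
        raise ValueError("block_size must be positive")
    if block_size > len(ids):
        raise ValueError("block_size exceeds the number of ids")
    return itertools.combinations(tuple(ids), block_size)


@dataclass(frozen=True)
class BlockScore:
    """A candidate within-stratum block and its propensity-score gap."""

    members: tuple
    ps_gap: float

    def __post_init__(self) -> None:
        if self.ps_gap < 0:
            raise ValueError("ps_gap must be non-negative")


def score_blocks(stratum_covariates: pd.DataFrame, block_size: int,
                 cap: int = DEFAULT_CAP, chunk_size: int = 50_000) -> list[BlockScore]:
    """Score every possible block of a stratum by its propensity-score gap.

    For each size-``block_size`` subset of the stratum, block membership is
    regressed on the covariates and the gap is the absolute difference in
    mean fitted probability between in-block and out-of-block subjects.
    Returns all C(n, block_size) blocks sorted ascending by gap, ties broken
    lexicographically by membership. Subjects are taken in ascending-id
    order so the result is independent of input row order.

    Raises :class:`EnumerationCapError` when the enumeration exceeds ``cap``
    (use ``constrained_random_allocate`` or raise the cap explicitly).
    """
    stratum_covariates = stratum_covariates.sort_index()
    ids = tuple(stratum_covariates.index)
    n = len(ids)
    total = math.comb(n, block_size)
    if total > cap:
        raise EnumerationCapError(
            f"C({n}, {block_size}) = {total} blocks exceeds cap {cap}; raise the cap "
            "or use constrained_random_allocate"
        )
    X = _design(stratum_covariates)
    members: list[tuple] = []
    gaps = np.empty(total)
    pos = 0
    for chunk in _chunked(itertools.combinations(range(n), block_size), chunk_size):
        Y = np.zeros((len(chunk), n))
        rows = np.repeat(np.arange(len(chunk)), block_size)
        cols = np.fromiter(itertools.chain.from_iterable(chunk), dtype=int,
                           count=len(chunk) * block_size)
        Y[rows, cols] = 1.0
        _, P, _, _ = _fit_many(X, Y)
        in_mean = (P * Y).sum(axis=1) / block_size
        out_mean = (P * (1.0 - Y)).sum(axis=1) / (n - block_size)
        gaps[pos : pos + len(chunk)] = np.abs(in_mean - out_mean)
        members.extend(tuple(ids[c] for c in combo) for combo in chunk)
        pos += len(chunk)
    order = sorted(range(total), key=lambda i: (gaps[i], members[i]))
    return [BlockScore(members=members[i], ps_gap=float(gaps[i])) for i in order]


def _chunked(iterable: Iterable, size: int) -> Iterator[list]:
    it = iter(iterable)
    while chunk := list(itertools.islice(it, size)):
        yield chunk


T = TypeVar("T")


def select_disjoint(sorted_items: Sequence[T], k: int,
                    members: Callable[[T], Iterable] = lambda item: item.members) -> list[T]:
    """Greedily keep the first ``k`` pairwise-disjoint items of a sorted list.

    Scans in the given order, keeping an item iff its member-set shares
    nothing with every item already kept. Raises if the scan is exhausted
    before ``k`` disjoint items are found.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    chosen: list[T] = []
    used: set = set()
    for item in sorted_items:
        mset = set(members(item))
        if used & mset:
            continue
        chosen.append(item)
        used |= mset
        if len(chosen) == k:
            return chosen
    raise ValueError(f"only {len(chosen)} disjoint items found, needed {k}")


@dataclass(frozen=True)
class BatchCombo:
    """A (case block, control block) pairing scored as a candidate batch."""

    case_members: tuple
    control_members: tuple
    between_gap: float
    within_gap: float
    between_rank: float
    within_rank: float

    @property
    def avg_rank(self) -> float:
        return (self.between_rank + self.within_rank) / 2.0

    @property
    def members(self) -> tuple:
        return self.case_members + self.control_members

    @property
    def blocks(self) -> tuple:
        """The pair of blocks, tagged by stratum, for disjoint selection."""
        return ((CASE, self.case_members), (CONTROL, self.control_members))


def score_batch_combos(case_blocks: Sequence[tuple], control_blocks: Sequence[tuple],
                       cohort: Cohort) -> list[BatchCombo]:
    """Score all pairings of case blocks with control blocks as batches.

    For each of the k*k pairs, batch membership (the union of the two
    blocks) is regressed on age and HbA1c over the whole cohort — case
    status is not a covariate because the design is balanced. The
    between-batch gap compares mean fitted probability inside vs outside
    the batch; the within-batch gap compares the batch's cases vs its
    controls. Both gaps are ranked ascending (midranks on ties) and combos
    are sorted by the average of the two ranks, ties broken by
    (between_gap, membership).
    """
    for blocks, label in ((case_blocks, "case"), (control_blocks, "control")):
        seen: set = set()
        for b in blocks:
            if seen & set(b):
                raise ValueError(f"{label} blocks overlap")
            seen |= set(b)
    cov = cohort.covariates().sort_index()
    ids = list(cov.index)
    id_pos = {sid: i for i, sid in enumerate(ids)}
    case_set = set(cohort.cases)
    X = _design(cov)

    pairs = [(tuple(sorted(cb)), tuple(sorted(gb)))
             for cb in case_blocks for gb in control_blocks]
    Y = np.zeros((len(pairs), len(ids)))
    for r, (cb, gb) in enumerate(pairs):
        for sid in cb + gb:
            Y[r, id_pos[sid]] = 1.0
    _, P, _, _ = _fit_many(X, Y)

    is_case = np.array([sid in case_set for sid in ids])
    between = np.empty(len(pairs))
    within = np.empty(len(pairs))
    for r in range(len(pairs)):
        inb = Y[r] == 1.0
        between[r] = abs(P[r, inb].mean() - P[r, ~inb].mean())
        within[r] = abs(P[r, inb & is_case].mean() - P[r, inb & ~is_case].mean())
    # Mathematically tied pairings (e.g. complementary batches) differ only
    # in rounding noise; rank on rounded gaps so midranks catch real ties.
    b_rank = rankdata(np.round(between, 10), method="average")
    w_rank = rankdata(np.round(within, 10), method="average")

    combos = [
        BatchCombo(case_members=cb, control_members=gb,
                   between_gap=float(between[r]), within_gap=float(within[r]),
                   between_rank=float(b_rank[r]), within_rank=float(w_rank[r]))
        for r, (cb, gb) in enumerate(pairs)
    ]
    combos.sort(key=lambda c: (c.avg_rank, c.between_gap, c.members))
    return combos


# ---------------------------------------------------------------------------
# Allocators
# ---------------------------------------------------------------------------


@dataclass
class BatchAssignment:
    """A complete subject-to-batch assignment.

    ``batches`` maps subject id to a batch label in 1..n_batches; under the
    balanced strategies every batch holds equal numbers of cases and
    controls.
    """

    batches: pd.Series = field(repr=False)
    strategy: str = "optimal"

    def __post_init__(self) -> None:
        if not self.batches.index.is_unique:
            raise ValueError("duplicate subject ids in assignment")
        self.batches = self.batches.astype(int)

    @property
    def n_batches(self) -> int:
        return int(self.batches.max())

    @property
    def labels(self) -> list[int]:
        return sorted(self.batches.unique())

    def members(self, batch: int) -> pd.Index:
        return self.batches.index[self.batches == batch]

    def indicator(self, batch: int) -> np.ndarray:
        return (self.batches == batch).to_numpy(dtype=float)

    def validate_balanced(self, cohort: Cohort) -> None:
        """Check full coverage and equal case/control counts per batch."""
        if set(self.batches.index) != set(cohort.subject_ids):
            raise ValueError("assignment does not cover the cohort exactly")
        k = self.n_batches
        cases = set(cohort.cases)
        for b in range(1, k + 1):
            mem = self.members(b)
            n_case = sum(sid in cases for sid in mem)
            if n_case != len(cohort.cases) // k or len(mem) - n_case != len(cohort.controls) // k:
                raise ValueError(f"batch {b} is not balanced")

    def to_frame(self, cohort: Cohort | None = None) -> pd.DataFrame:
        out = pd.DataFrame({"subject_id": self.batches.index, "batch": self.batches.values})
        if cohort is not None:
            out.insert(1, "group", cohort.frame.loc[out["subject_id"], "group"].values)
        return out


def _check_divisible(count: int, n_batches: int, what: str) -> int:
    if n_batches <= 0:
        raise ValueError("n_batches must be positive")
    if count % n_batches:
        raise ValueError(f"{what} size {count} not divisible by {n_batches} batches")
    return count // n_batches


def optimal_allocate(cohort: Cohort, n_batches: int = 3, cap: int = DEFAULT_CAP) -> BatchAssignment:
    """Propensity-score-optimal balanced allocation (deterministic).

    Per stratum: score every possible block, then greedily keep the
    ``n_batches`` lowest-gap disjoint blocks. Across strata: score all
    block pairings as candidate batches, sort by average rank of the
    between-batch and within-batch gaps, and greedily keep ``n_batches``
    pairings that reuse no block. Batch labels 1..k follow selection order.
    """
    chosen_blocks: dict[str, list[tuple]] = {}
    for group in (CASE, CONTROL):
        strat = cohort.stratum(group)
        block_size = _check_divisible(len(strat), n_batches, group)
        scores = score_blocks(strat, block_size, cap=cap)
        chosen_blocks[group] = [b.members for b in select_disjoint(scores, n_batches)]

    combos = score_batch_combos(chosen_blocks[CASE], chosen_blocks[CONTROL], cohort)
    selected = select_disjoint(combos, n_batches, members=lambda c: c.blocks)

    assignment: dict = {}
    for label, combo in enumerate(selected, start=1):
        for sid in combo.members:
            assignment[sid] = label
    batches = pd.Series(assignment).sort_index()
    out = BatchAssignment(batches=batches, strategy="optimal")
    out.validate_balanced(cohort)
    return out


def _seed_sequence(seed) -> np.random.SeedSequence:
    return seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)


def random_allocate(cohort: Cohort, n_batches: int = 3, seed=0) -> BatchAssignment:
    """Simple randomization: a random permutation of a balanced label vector."""
    ids = sorted(cohort.subject_ids)
    per_batch = _check_divisible(len(ids), n_batches, "cohort")
    labels = np.repeat(np.arange(1, n_batches + 1), per_batch)
    rng = np.random.default_rng(_seed_sequence(seed))
    labels = rng.permutation(labels)
    return BatchAssignment(batches=pd.Series(labels, index=pd.Index(ids)).sort_index(),
                           strategy="random")


def stratified_allocate(cohort: Cohort, n_batches: int = 3, seed=0) -> BatchAssignment:
    """Stratified randomization: independent label permutation per stratum.

    Preserves the balanced design (equal cases and controls per batch).
    Sub-seeds for the two strata are spawned from ``seed``.
    """
    ss = _seed_sequence(seed)
    case_ss, control_ss = ss.spawn(2)
    parts = []
    for group, sub in ((CASE, case_ss), (CONTROL, control_ss)):
        ids = sorted(cohort.stratum(group).index)
        per_batch = _check_divisible(len(ids), n_batches, group)
        labels = np.repeat(np.arange(1, n_batches + 1), per_batch)
        rng = np.random.default_rng(sub)
        parts.append(pd.Series(rng.permutation(labels), index=pd.Index(ids)))
    batches = pd.concat(parts).sort_index()
    out = BatchAssignment(batches=batches, strategy="stratified")
    out.validate_balanced(cohort)
    return out


def _candidate_metric(cohort: Cohort, assignments: Sequence[BatchAssignment]) -> np.ndarray:
    """Balance metric per candidate: sum over batches of between + within gaps.

    One propensity fit per (candidate, batch) over all cohort subjects with
    the in-batch indicator as outcome; all fits share the design, so they
    run as one batched IRLS call.
    """
    cov = cohort.covariates().sort_index()
    ids = list(cov.index)
    X = _design(cov)
    is_case = np.array([sid in set(cohort.cases) for sid in ids])
    k = assignments[0].n_batches
    Y = np.stack([
        (a.batches.reindex(ids).to_numpy() == b).astype(float)
        for a in assignments for b in range(1, k + 1)
    ])
    _, P, _, _ = _fit_many(X, Y)
    metrics = np.zeros(len(assignments))
    for r in range(Y.shape[0]):
        inb = Y[r] == 1.0
        between = abs(P[r, inb].mean() - P[r, ~inb].mean())
        within = abs(P[r, inb & is_case].mean() - P[r, inb & ~is_case].mean())
        metrics[r // k] += between + within
    return metrics


def constrained_random_allocate(cohort: Cohort, n_batches: int = 3,
                                n_candidates: int = 100, seed=0,
                                return_details: bool = False):
    """Best-of-R constrained randomization.

    Draws ``n_candidates`` stratified allocations from sub-seeds spawned
    from ``seed``, scores each by the summed between- plus within-batch
    propensity-score gaps, and returns the minimizer (first on ties).
    A computationally feasible stand-in for the exhaustive optimal search.
    """
    if n_candidates < 1:
        raise ValueError("n_candidates must be at least 1")
    children = _seed_sequence(seed).spawn(n_candidates)
    candidates = [stratified_allocate(cohort, n_batches, seed=child) for child in children]
    metrics = _candidate_metric(cohort, candidates)
    best = int(np.argmin(metrics))
    chosen = BatchAssignment(batches=candidates[best].batches, strategy="constrained")
    if return_details:
        return chosen, metrics
    return chosen
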