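"""Sample partitioning and characteristic-wavelength selection.

Kennard-Stone splits samples by max-min Euclidean distance.  Four screening
families pick informative bands:

* SPA — successive projections: greedy chains that maximise the projection
  norm onto the orthogonal complement of the bands already chosen, scored by
  validation RMSE of a multilinear model.
* SFLA — shuffled frog leaping: a memetic search over binary band subsets.
* VCPA — binary matrix sampling with an exponentially decreasing function
  (EDF) that shrinks the surviving band pool, optionally refined by a
  genetic algorithm or by IRIV (iteratively retains informative variables).

All stochastic selectors take an explicit seed and are bit-reproducible; the
shared objective is the cross-validated RMSE of an inner regressor.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import mannwhitneyu
from sklearn.cross_decomposition import PLSRegression

from .synthetic import ParameterError, WavelengthGrid

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Kennard-Stone partitioning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalSplit:
    """Disjoint calibration/prediction sample indices."""

    calibration: np.ndarray
    prediction: np.ndarray

    def __post_init__(self):
        cal = np.asarray(self.calibration, int)
        pred = np.asarray(self.prediction, int)
        if np.intersect1d(cal, pred).size:
            raise ParameterError("calibration and prediction sets overlap")
        object.__setattr__(self, "calibration", cal)
        object.__setattr__(self, "prediction", pred)


def kennard_stone(X: np.ndarray, cal_fraction: float = 0.75) -> CalSplit:
    """Deterministic max-min distance partition into calibration/prediction.

    The first two picks are the sample pair at maximal Euclidean distance;
    every later pick maximises its minimum distance to the already-picked
    samples.  Ties resolve to the lowest index.
    """
    X = np.asarray(X, float)
    n = X.shape[0]
    if n < 2:
        raise ParameterError("need at least 2 samples to split")
    if not 0.0 < cal_fraction < 1.0:
        raise ParameterError("cal_fraction must lie strictly in (0, 1)")
    n_cal = int(round(cal_fraction * n))
    if n_cal < 2 or n_cal >= n:
        raise ParameterError(
            f"cal_fraction {cal_fraction} leaves an empty calibration or "
            f"prediction set for n = {n}")

    sq = np.sum(X ** 2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.fill_diagonal(d2, -np.inf)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    picked = [min(i, j), max(i, j)]
    min_d = np.minimum(d2[:, picked[0]], d2[:, picked[1]])
    min_d[picked] = -np.inf
    while len(picked) < n_cal:
        nxt = int(np.argmax(min_d))
        picked.append(nxt)
        min_d = np.minimum(min_d, d2[:, nxt])
        min_d[nxt] = -np.inf
    cal = np.sort(picked)
    pred = np.setdiff1d(np.arange(n), cal)
    return CalSplit(cal, pred)


# ---------------------------------------------------------------------------
# Shared subset objective
# ---------------------------------------------------------------------------

def _cv_folds(n: int, folds: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    return [order[k::folds] for k in range(folds)]


def _mlr_cv_rmse(X: np.ndarray, y: np.ndarray, test_sets: list[np.ndarray]) -> float:
    n = len(y)
    resid = np.empty(n)
    ones = np.ones((n, 1))
    A = np.hstack([ones, X])
    for test in test_sets:
        train = np.setdiff1d(np.arange(n), test)
        coef, *_ = np.linalg.lstsq(A[train], y[train], rcond=None)
        resid[test] = A[test] @ coef - y[test]
    return float(np.sqrt(np.mean(resid ** 2)))


def _pls_cv_rmse(X: np.ndarray, y: np.ndarray, test_sets: list[np.ndarray],
                 max_components: int) -> float:
    n = len(y)
    resid = np.empty(n)
    for test in test_sets:
        train = np.setdiff1d(np.arange(n), test)
        ncomp = min(max_components, X.shape[1], len(train) - 1)
        model = PLSRegression(n_components=ncomp, scale=False)
        model.fit(X[train], y[train])
        resid[test] = model.predict(X[test]).ravel() - y[test]
    return float(np.sqrt(np.mean(resid ** 2)))


class SubsetFitness:
    """Cross-validated RMSE of an inner regressor on a band subset.

    Small subsets (<= ``mlr_threshold`` bands) are scored with multilinear
    regression; larger ones with PLS capped at ``max_pls_components`` latent
    variables.  Fold assignment is fixed by the seed, so the same subset
    always maps to the same fitness; evaluations are memoised.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, folds: int = 5,
                 seed: int = 0, max_pls_components: int = 10,
                 mlr_threshold: int = 10, force_mlr: bool = False):
        self.X = np.asarray(X, float)
        self.y = np.asarray(y, float)
        if folds < 2 or folds > len(self.y):
            raise ParameterError("folds must lie in [2, n_samples]")
        self.test_sets = _cv_folds(len(self.y), folds, seed)
        self.max_pls_components = max_pls_components
        self.mlr_threshold = mlr_threshold
        self.force_mlr = force_mlr
        self.seed = seed
        self._cache: dict[tuple, float] = {}
        self.n_evaluations = 0

    def __call__(self, indices) -> float:
        idx = tuple(sorted(int(i) for i in indices))
        if not idx:
            raise ParameterError("cannot score an empty band subset")
        if idx not in self._cache:
            Xs = self.X[:, list(idx)]
            if self.force_mlr or len(idx) <= self.mlr_threshold:
                rmse = _mlr_cv_rmse(Xs, self.y, self.test_sets)
            else:
                rmse = _pls_cv_rmse(Xs, self.y, self.test_sets,
                                    self.max_pls_components)
            self._cache[idx] = rmse
            self.n_evaluations += 1
        return self._cache[idx]


# ---------------------------------------------------------------------------
# Selection results
# ---------------------------------------------------------------------------

@dataclass
class SelectionResult:
    """Selected band subset with its objective trace."""

    algorithm: str
    indices: np.ndarray
    wavelengths_nm: np.ndarray
    fitness: float
    fitness_trace: list[float] = field(default_factory=list)
    n_bands_total: int = 0
    survivors: np.ndarray | None = None   # VCPA pool handed to refinement

    def __post_init__(self):
        idx = np.unique(np.asarray(self.indices, int))
        if idx.size == 0:
            raise ParameterError("selection produced an empty subset")
        self.indices = idx
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, float)

    @property
    def data_reduction_ratio(self) -> float:
        """Fraction of bands eliminated (the surplus-data elimination rate)."""
        if not self.n_bands_total:
            return float("nan")
        return 1.0 - self.indices.size / self.n_bands_total

    def to_json(self, path) -> None:
        payload = {
            "algorithm": self.algorithm,
            "indices": self.indices.tolist(),
            "wavelengths_nm": self.wavelengths_nm.tolist(),
            "fitness": self.fitness,
            "fitness_trace": list(map(float, self.fitness_trace)),
            "n_bands_total": self.n_bands_total,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SelectionResult":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["algorithm"], np.array(d["indices"]),
                   np.array(d["wavelengths_nm"]), d["fitness"],
                   d["fitness_trace"], d["n_bands_total"])


def _wavelengths(grid: WavelengthGrid | None, indices, n_bands: int) -> np.ndarray:
    if grid is None:
        return np.asarray(sorted(set(int(i) for i in indices)), float)
    return grid.wavelengths_nm[np.asarray(sorted(set(int(i) for i in indices)))]


# ---------------------------------------------------------------------------
# SPA — successive projections algorithm
# ---------------------------------------------------------------------------

def spa_chain(X: np.ndarray, start: int, k: int) -> list[int]:
    """Greedy SPA chain of length ``k`` from a starting column.

    At each step every unselected column is projected onto the orthogonal
    complement of the selected span (iterative rank-1 deflation) and the
    column with the largest residual norm joins the chain.
    """
    P = np.array(X, float)
    n_bands = P.shape[1]
    chain = [start]
    for _ in range(k - 1):
        v = P[:, chain[-1]].copy()
        vv = float(v @ v)
        if vv <= 1e-300:
            break
        P -= np.outer(v, (v @ P) / vv)
        norms = np.einsum("ij,ij->j", P, P)
        norms[chain] = -1.0
        nxt = int(np.argmax(norms))
        if norms[nxt] <= 1e-12:   # remaining columns are collinear with the span
            break
        chain.append(nxt)
    return chain


def spa_select(Xcal: np.ndarray, ycal: np.ndarray, kmin: int = 3,
               kmax: int | None = None, grid: WavelengthGrid | None = None,
               folds: int = 5, seed: int = 0) -> SelectionResult:
    """SPA over all start columns and chain lengths in [kmin, kmax].

    The winning subset is the chain with minimal cross-validated RMSE of a
    multilinear model; ties resolve to fewer bands, then lower start column.
    """
    X = np.asarray(Xcal, float)
    n, b = X.shape
    if kmax is None:
        kmax = min(b, n - 1, 25)
    if kmax < kmin:
        raise ParameterError("kmax must be >= kmin")
    if kmin < 1 or kmax > min(b, n - 1):
        raise ParameterError("chain lengths must satisfy 1 <= kmin <= kmax "
                             "<= min(bands, samples - 1)")
    fitness = SubsetFitness(X, ycal, folds=folds, seed=seed, force_mlr=True)
    best = (np.inf, np.inf, np.inf, None)
    trace = []
    for start in range(b):
        chain = spa_chain(X, start, kmax)
        for k in range(kmin, min(kmax, len(chain)) + 1):
            subset = chain[:k]
            rmse = fitness(subset)
            key = (rmse, k, start)
            if key < best[:3]:
                best = (rmse, k, start, subset)
        trace.append(best[0])
    rmse, _, _, subset = best
    return SelectionResult("SPA", np.array(subset), _wavelengths(grid, subset, b),
                           rmse, trace, n_bands_total=b)


# ---------------------------------------------------------------------------
# SFLA — shuffled frog leaping
# ---------------------------------------------------------------------------

def _repair(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if not mask.any():
        mask = mask.copy()
        mask[rng.integers(mask.size)] = True
        log.debug("repaired empty frog by activating one random band")
    return mask


def _leap(worst: np.ndarray, toward: np.ndarray, rng: np.random.Generator
          ) -> np.ndarray:
    take = rng.random(worst.size) < 0.5
    return np.where(take, toward, worst)


def sfla_select(Xcal: np.ndarray, ycal: np.ndarray,
                fitness: SubsetFitness | None = None, memeplexes: int = 5,
                frogs_per: int = 10, iterations: int = 50, seed: int = 0,
                init_prob: float = 0.1, grid: WavelengthGrid | None = None
                ) -> SelectionResult:
    """Binary SFLA over band subsets with elitist best-ever tracking.

    Frogs (binary inclusion vectors) are ranked by fitness and dealt into
    memeplexes round-robin.  Each memeplex improves its worst frog by a
    leap toward the local best, falling back to the global best, then to a
    random re-draw.  The global best fitness is non-increasing by elitism.
    """
    X = np.asarray(Xcal, float)
    n, b = X.shape
    pop_size = memeplexes * frogs_per
    if pop_size < 4:
        raise ParameterError("population (memeplexes x frogs_per) must be >= 4")
    fitness = fitness or SubsetFitness(X, ycal, seed=seed)
    rng = np.random.default_rng(seed)

    frogs = [_repair(rng.random(b) < init_prob, rng) for _ in range(pop_size)]
    scores = [fitness(np.flatnonzero(f)) for f in frogs]
    best_mask = frogs[int(np.argmin(scores))].copy()
    best_score = min(scores)
    trace = []

    for _ in range(iterations):
        order = np.argsort(scores, kind="stable")
        frogs = [frogs[i] for i in order]
        scores = [scores[i] for i in order]
        for m in range(memeplexes):
            ids = list(range(m, pop_size, memeplexes))
            worst_id = ids[-1]
            local_best = frogs[ids[0]]
            worst = frogs[worst_id]
            w_score = scores[worst_id]
            for target in (local_best, best_mask, None):
                cand = (_leap(worst, target, rng) if target is not None
                        else (rng.random(b) < init_prob))
                cand = _repair(cand, rng)
                c_score = fitness(np.flatnonzero(cand))
                if c_score < w_score or target is None:
                    frogs[worst_id] = cand
                    scores[worst_id] = c_score
                    break
        i_best = int(np.argmin(scores))
        if scores[i_best] < best_score:
            best_score = scores[i_best]
            best_mask = frogs[i_best].copy()
        trace.append(best_score)

    idx = np.flatnonzero(best_mask)
    return SelectionResult("SFLA", idx, _wavelengths(grid, idx, b), best_score,
                           trace, n_bands_total=b)


# ---------------------------------------------------------------------------
# VCPA — binary matrix sampling with EDF shrinkage
# ---------------------------------------------------------------------------

def edf_schedule(n_bands: int, final_size: int, loops: int) -> np.ndarray:
    """Surviving-band counts round(n0 * r**(k/K)), r = final/n0, k = 1..K."""
    ratio = final_size / n_bands
    ks = np.arange(1, loops + 1)
    counts = np.round(n_bands * ratio ** (ks / loops)).astype(int)
    return np.minimum.accumulate(counts)


def vcpa_select(Xcal: np.ndarray, ycal: np.ndarray,
                fitness: SubsetFitness | None = None, n_bms: int = 500,
                edf_loops: int = 10, keep_top_fraction: float = 0.1,
                final_size: int = 100, seed: int = 0,
                grid: WavelengthGrid | None = None) -> SelectionResult:
    """Variable combination population analysis.

    Each loop draws ``n_bms`` random binary subsets (inclusion probability
    0.5) over the surviving bands, keeps the best ``keep_top_fraction`` by
    fitness, scores bands by their frequency in the kept subsets and shrinks
    the pool along the EDF schedule.  Returns the best subset of the final
    loop; the remaining pool is exposed for GA/IRIV refinement.
    """
    X = np.asarray(Xcal, float)
    n, b = X.shape
    if edf_loops < 2:
        raise ParameterError("edf_loops must be >= 2")
    if final_size >= b:
        raise ParameterError("final_size must be smaller than the band count")
    fitness = fitness or SubsetFitness(X, ycal, seed=seed)
    rng = np.random.default_rng(seed)
    schedule = edf_schedule(b, final_size, edf_loops)
    survivors = np.arange(b)
    trace = []
    best_final = (np.inf, None)

    for loop, target in enumerate(schedule):
        M = rng.random((n_bms, survivors.size)) < 0.5
        for r in range(n_bms):
            M[r] = _repair(M[r], rng)
        row_scores = np.array([fitness(survivors[M[r]]) for r in range(n_bms)])
        n_keep = max(1, int(round(keep_top_fraction * n_bms)))
        keep = np.argsort(row_scores, kind="stable")[:n_keep]
        trace.append(float(row_scores[keep[0]]))
        if loop == len(schedule) - 1:
            best_row = keep[0]
            best_final = (float(row_scores[best_row]), survivors[M[best_row]])
        freq = M[keep].mean(axis=0)
        # highest-frequency bands survive; stable ordering breaks ties by index
        order = np.argsort(-freq, kind="stable")[:target]
        survivors = np.sort(survivors[order])

    score, idx = best_final
    return SelectionResult("VCPA", idx, _wavelengths(grid, idx, b), score,
                           trace, n_bands_total=b, survivors=survivors)


# ---------------------------------------------------------------------------
# Refinement of VCPA survivors: GA or IRIV
# ---------------------------------------------------------------------------

def _ga_refine(survivors, fitness, seed, population=30, generations=100,
               crossover=0.9, mutation=0.05, elitism=1, tournament=3,
               initial=None):
    rng = np.random.default_rng(seed)
    s = np.asarray(survivors, int)
    b = s.size
    if initial is not None:
        pop = [_repair(np.asarray(m, bool).copy(), rng) for m in initial]
        population = len(pop)
    else:
        pop = [_repair(rng.random(b) < 0.5, rng) for _ in range(population)]
    scores = np.array([fitness(s[m]) for m in pop])
    trace = []

    def tourney():
        picks = rng.integers(population, size=tournament)
        return pop[picks[np.argmin(scores[picks])]]

    for _ in range(generations):
        order = np.argsort(scores, kind="stable")
        new_pop = [pop[i].copy() for i in order[:elitism]]
        while len(new_pop) < population:
            p1, p2 = tourney(), tourney()
            if rng.random() < crossover:
                take = rng.random(b) < 0.5
                child = np.where(take, p1, p2)
            else:
                child = p1.copy()
            flip = rng.random(b) < mutation
            child = np.logical_xor(child, flip)
            new_pop.append(_repair(child, rng))
        pop = new_pop
        scores = np.array([fitness(s[m]) for m in pop])
        trace.append(float(scores.min()))
    best = pop[int(np.argmin(scores))]
    return s[best], float(scores.min()), trace


def _iriv_refine(survivors, fitness, seed, n_draws=100, alpha=0.05,
                 max_rounds=10):
    rng = np.random.default_rng(seed)
    current = np.asarray(survivors, int)
    trace = []
    for _ in range(max_rounds):
        if current.size <= 2:
            break
        M = rng.random((n_draws, current.size)) < 0.5
        for r in range(n_draws):
            M[r] = _repair(M[r], rng)
        row_scores = np.array([fitness(current[M[r]]) for r in range(n_draws)])
        trace.append(float(row_scores.min()))
        keep = np.ones(current.size, bool)
        n_interfering = n_uninformative = 0
        for j in range(current.size):
            with_j = row_scores[M[:, j]]
            without_j = row_scores[~M[:, j]]
            if with_j.size < 3 or without_j.size < 3:
                continue
            helps = with_j.mean() < without_j.mean()
            if helps:
                continue  # strongly or weakly informative: retained
            # inclusion harms: interfering (significant) or uninformative
            keep[j] = False
            p = mannwhitneyu(with_j, without_j, alternative="greater").pvalue
            if p < alpha:
                n_interfering += 1
            else:
                n_uninformative += 1
        if n_interfering or n_uninformative:
            log.debug("IRIV round: dropping %d interfering, %d uninformative "
                      "bands", n_interfering, n_uninformative)
        if keep.all():
            break
        if not keep.any():
            keep[np.argmin([fitness(current[[j]]) for j in range(current.size)])] = True
        candidate = current[keep]
        # retain-informative guard: a round of drops must not hurt the model
        if fitness(candidate) > fitness(current):
            break
        current = candidate

    # backward elimination on the retained informative bands
    cur_score = fitness(current)
    improved = True
    while improved and current.size > 1:
        improved = False
        drop_scores = [fitness(np.delete(current, j)) for j in range(current.size)]
        j_best = int(np.argmin(drop_scores))
        if drop_scores[j_best] < cur_score:
            current = np.delete(current, j_best)
            cur_score = drop_scores[j_best]
            trace.append(cur_score)
            improved = True
    return current, cur_score, trace


def refine_subset(Xcal: np.ndarray, ycal: np.ndarray, survivors, mode: str,
                  fitness: SubsetFitness | None = None, params: dict | None = None,
                  seed: int = 0, grid: WavelengthGrid | None = None
                  ) -> SelectionResult:
    """Refine a VCPA survivor pool with a genetic algorithm or IRIV.

    GA evolves binary chromosomes over the survivors (tournament selection,
    uniform crossover, bit-flip mutation, elitism).  IRIV repeatedly draws
    random inclusion matrices, compares the fitness distributions of subsets
    with vs without each band (Mann-Whitney), drops uninformative and
    interfering bands, then finishes with backward elimination.
    """
    if isinstance(survivors, SelectionResult):
        survivors = survivors.survivors if survivors.survivors is not None \
            else survivors.indices
    survivors = np.asarray(survivors, int)
    if survivors.size == 0:
        raise ParameterError("survivor pool is empty")
    X = np.asarray(Xcal, float)
    fitness = fitness or SubsetFitness(X, ycal, seed=seed)
    params = params or {}
    if mode.upper() == "GA":
        idx, score, trace = _ga_refine(survivors, fitness, seed, **params)
        name = "VCPA-GA"
    elif mode.upper() == "IRIV":
        idx, score, trace = _iriv_refine(survivors, fitness, seed, **params)
        name = "VCPA-IRIV"
    else:
        raise ParameterError(f"unknown refinement mode {mode!r}")
    return SelectionResult(name, idx, _wavelengths(grid, idx, X.shape[1]),
                           score, trace, n_bands_total=X.shape[1])
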