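"""The UbL score: GA feature selection plus LDA classification.

From the discovery signature, a small panel of proteins is expanded into
(protein, modifier) variables -- a protein modified by both ubiquitin and
SUMO-1 contributes two variables.  A binary-chromosome genetic algorithm
is run many times (with jittered mutation rates) to select predictive
variable subsets; variables are ranked by how often they appear in the
best-of-run solutions, the ranking is cut into nested subsets of
increasing size, and each subset is evaluated by cross-validated linear
discriminant analysis.  The winning subset's LDA yields, for any sample,
a linear score (alpha*R1 + ... + omega*Rn) and a posterior probability of
belonging to the resistant class; samples are labeled sensitive below
50%, resistant above.

The LDA uses a pooled within-class covariance optionally shrunk toward
its diagonal (useful when the variable count approaches the sample
count); coefficients are Sigma^-1 (mu_resistant - mu_sensitive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = ["VariableMatrix", "expand_variables", "LDAModel", "lda_fit",
           "lda_predict_proba", "classify_sample", "Prediction",
           "cv_accuracy", "GAConfig", "GASolutionSet", "ga_select",
           "NestedSubsets", "build_nested_subsets", "evaluate_subsets"]

SENSITIVE, RESISTANT = "sensitive", "resistant"


# ---------------------------------------------------------------------------
# variable expansion

@dataclass
class VariableMatrix:
    """Samples x variables measurement matrix with class labels.

    Variables are named ``"<protein>|<modifier>"``.  ``labels`` maps each
    training sample to sensitive/resistant; unlabeled (NaN) samples may be
    present for prediction only.
    """

    X: pd.DataFrame
    labels: pd.Series

    @property
    def variables(self) -> list[str]:
        return self.X.columns.tolist()

    def labeled(self) -> tuple[pd.DataFrame, pd.Series]:
        mask = self.labels.notna()
        return self.X.loc[mask], self.labels.loc[mask]


def variable_name(protein: str, modifier: str) -> str:
    return f"{protein}|{modifier}"


def expand_variables(selection: list[tuple[str, tuple[str, ...]]],
                     measurements: pd.DataFrame,
                     labels: pd.Series) -> VariableMatrix:
    """Expand a protein panel into (protein, modifier) variables.

    ``selection`` lists (protein, modifiers-flagged) entries; a protein
    flagged for both UbLs contributes one variable per modifier (so 7
    SUMO-only + 9 Ub-only + 7 dual proteins give 30 variables).
    ``measurements`` has samples as rows and a (protein, modifier)
    MultiIndex on columns; a missing required column is an error naming
    the pair.
    """
    cols = []
    names = []
    for protein, modifiers in selection:
        if not modifiers:
            raise ValueError(f"protein {protein!r} flagged for no modifier")
        for modifier in modifiers:
            key = (protein, modifier)
            if key not in measurements.columns:
                raise KeyError("no measurement for protein "
                               f"{protein!r} / modifier {modifier!r}")
            cols.append(key)
            names.append(variable_name(protein, modifier))
    if len(set(names)) != len(names):
        raise ValueError("duplicate (protein, modifier) in selection")
    X = measurements[cols].copy()
    X.columns = names
    return VariableMatrix(X=X, labels=labels.reindex(X.index))


# ---------------------------------------------------------------------------
# linear discriminant analysis

@dataclass
class LDAModel:
    """Fisher LDA with shared (optionally shrunk) covariance.

    The decision score of a sample x is ``coef . x + intercept``; the
    posterior probability of the resistant class is the logistic of the
    score (exact for Gaussian class-conditionals with equal covariance).
    """

    variables: list[str]
    coef: np.ndarray
    intercept: float
    class_means: dict[str, np.ndarray]
    priors: dict[str, float]
    covariance: np.ndarray
    shrinkage: float


@dataclass(frozen=True)
class Prediction:
    sample_id: str
    probability_resistant: float
    predicted_class: str  # sensitive | resistant | indeterminate


def _auto_shrinkage(Xc: np.ndarray) -> float:
    """Schafer-Strimmer analytic shrinkage intensity toward the diagonal.

    ``Xc`` holds within-class-centered observations.  Returns gamma in
    [0, 1] minimizing the expected squared loss of
    (1-gamma) S + gamma diag(S) against the true covariance.
    """
    n, p = Xc.shape
    if p < 2 or n < 3:
        return 0.0
    s = Xc.T @ Xc / (n - 1)
    w = Xc[:, :, None] * Xc[:, None, :]          # n x p x p products
    var_s = w.var(axis=0, ddof=1) * n / (n - 1) ** 2
    off = ~np.eye(p, dtype=bool)
    denom = (s[off] ** 2).sum()
    if denom <= 0:
        return 0.0
    return float(np.clip(var_s[off].sum() / denom, 0.0, 1.0))


def _fit_core(X: np.ndarray, y01: np.ndarray, shrinkage) -> tuple[np.ndarray, float, float]:
    """Fit coefficients and intercept; y01 is 0 = sensitive, 1 = resistant.

    Returns (coef, intercept, gamma).  Classes of size 1 contribute a
    zero scatter (their mean is still used), which keeps small
    cross-validation training folds well-defined.
    """
    n, p = X.shape
    m0 = X[y01 == 0].mean(axis=0)
    m1 = X[y01 == 1].mean(axis=0)
    Xc = X.copy()
    Xc[y01 == 0] -= m0
    Xc[y01 == 1] -= m1
    dof = max(n - 2, 1)
    S = Xc.T @ Xc / dof
    if shrinkage == "auto":
        gamma = _auto_shrinkage(Xc)
    else:
        gamma = float(shrinkage)
        if not 0.0 <= gamma <= 1.0:
            raise ValueError("shrinkage must be in [0, 1]")
    if gamma > 0.0:
        S = (1.0 - gamma) * S + gamma * np.diag(np.diag(S))
    diag = np.diag(S)
    if (diag == 0.0).any():
        # zero within-class variance (perfect separation): floor the
        # variance so the discriminant direction stays defined
        eps = 1e-9 * (diag[diag > 0].mean() if (diag > 0).any() else 1.0)
        S = S + np.diag(np.where(diag == 0.0, eps, 0.0))
    delta = m1 - m0
    try:
        w = np.linalg.solve(S, delta)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "singular pooled covariance; increase shrinkage "
            "(e.g. shrinkage='auto')")
    if not np.all(np.isfinite(w)):
        raise np.linalg.LinAlgError(
            "ill-conditioned pooled covariance; increase shrinkage")
    n1 = int(y01.sum())
    pi1 = n1 / n
    b = -0.5 * float(w @ (m0 + m1)) + np.log(pi1 / (1.0 - pi1))
    return w, b, gamma


def _as_y01(labels: pd.Series | np.ndarray) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "if":
        return arr.astype(int)
    out = np.where(arr == RESISTANT, 1, np.where(arr == SENSITIVE, 0, -1))
    if (out < 0).any():
        bad = sorted(set(arr[out < 0]))
        raise ValueError(f"unknown class labels {bad}")
    return out


def lda_fit(X: pd.DataFrame | np.ndarray, labels=None,
            shrinkage="auto") -> LDAModel:
    """Fit the LDA on labeled samples.

    ``X`` may be a :class:`VariableMatrix` (labels taken from it), or a
    DataFrame/array with ``labels`` given separately.  Constant
    (zero-variance) variables are dropped with a warning; both classes
    must be present with at least 2 samples each.
    """
    if isinstance(X, VariableMatrix):
        Xdf, labels = X.labeled()
    elif isinstance(X, pd.DataFrame):
        Xdf = X
    else:
        Xdf = pd.DataFrame(np.asarray(X, dtype=float))
        Xdf.columns = [f"v{i}" for i in range(Xdf.shape[1])]
    if labels is None:
        raise ValueError("labels required")
    y01 = _as_y01(labels)
    classes, counts = np.unique(y01, return_counts=True)
    if set(classes) != {0, 1}:
        raise ValueError("both classes (sensitive, resistant) must be "
                         "present in the training labels")
    if counts.min() < 2:
        raise ValueError("need at least 2 samples per class")
    arr = Xdf.values.astype(float)
    const = arr.std(axis=0) == 0.0
    if const.any():
        dropped = [c for c, flag in zip(Xdf.columns, const) if flag]
        warnings.warn(f"dropping constant variables {dropped}")
        Xdf = Xdf.loc[:, ~const]
        arr = arr[:, ~const]
        if arr.shape[1] == 0:
            raise ValueError("all variables constant")
    w, b, gamma = _fit_core(arr, y01, shrinkage)
    m0 = arr[y01 == 0].mean(axis=0)
    m1 = arr[y01 == 1].mean(axis=0)
    Xc = arr.copy()
    Xc[y01 == 0] -= m0
    Xc[y01 == 1] -= m1
    S = Xc.T @ Xc / max(arr.shape[0] - 2, 1)
    if gamma > 0:
        S = (1 - gamma) * S + gamma * np.diag(np.diag(S))
    n = arr.shape[0]
    return LDAModel(variables=list(Xdf.columns), coef=w, intercept=b,
                    class_means={SENSITIVE: m0, RESISTANT: m1},
                    priors={SENSITIVE: float((y01 == 0).mean()),
                            RESISTANT: float((y01 == 1).mean())},
                    covariance=S, shrinkage=gamma)


def _posterior(model: LDAModel, x: np.ndarray) -> float:
    score = float(model.coef @ x + model.intercept)
    return float(expit(score))


def lda_predict_proba(model: LDAModel, x, sample_id: str = "sample",
                      ) -> Prediction:
    """Posterior probability of resistance for one sample vector."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size != len(model.variables):
        raise ValueError(f"sample has {x.size} values; model expects "
                         f"{len(model.variables)}")
    p = _posterior(model, x)
    return classify_from_probability(sample_id, p)


def classify_from_probability(sample_id: str, p: float) -> Prediction:
    if p < 0.5:
        cls = SENSITIVE
    elif p > 0.5:
        cls = RESISTANT
    else:
        cls = "indeterminate"
    return Prediction(sample_id=sample_id, probability_resistant=p,
                      predicted_class=cls)


def classify_sample(model: LDAModel, x, sample_id: str = "sample",
                    ) -> Prediction:
    """50%-rule classification: sensitive below 0.5, resistant above,
    indeterminate at exactly 0.5."""
    return lda_predict_proba(model, x, sample_id=sample_id)


# ---------------------------------------------------------------------------
# cross-validation

def _stratified_splits(y01: np.ndarray, train_frac: float, n_rep: int,
                       rng: np.random.Generator):
    """Seeded stratified train/test splits; folds whose training set
    would lose a class are redrawn (guaranteed impossible here because
    the split is stratified per class with at least one training
    member)."""
    idx0 = np.flatnonzero(y01 == 0)
    idx1 = np.flatnonzero(y01 == 1)
    for _ in range(n_rep):
        tr = []
        for idx in (idx0, idx1):
            perm = rng.permutation(idx)
            k = max(1, int(round(train_frac * idx.size)))
            k = min(k, idx.size - 1) if idx.size > 1 else k
            tr.append(perm[:k])
        train = np.concatenate(tr)
        mask = np.zeros(y01.size, dtype=bool)
        mask[train] = True
        yield mask, ~mask


def cv_accuracy(X, labels=None, subset=None, scheme="loocv",
                shrinkage="auto", seed: int = 0) -> float:
    """Cross-validated LDA classification accuracy.

    ``scheme`` is ``"loocv"`` or ``("split", train_frac, n_rep)`` (seeded,
    stratified).  ``subset`` restricts to the named (or integer-indexed)
    variables; it must be non-empty.
    """
    if isinstance(X, VariableMatrix):
        Xdf, labels = X.labeled()
        arr = Xdf.values.astype(float)
        names = Xdf.columns.tolist()
    elif isinstance(X, pd.DataFrame):
        arr = X.values.astype(float)
        names = X.columns.tolist()
    else:
        arr = np.asarray(X, dtype=float)
        names = list(range(arr.shape[1]))
    y01 = _as_y01(labels)
    if subset is not None:
        if len(subset) == 0:
            raise ValueError("empty variable subset")
        pos = [names.index(v) if not isinstance(v, (int, np.integer)) else int(v)
               for v in subset]
        arr = arr[:, pos]
    return _cv_accuracy_core(arr, y01, scheme, shrinkage, seed)


def _cv_accuracy_core(arr: np.ndarray, y01: np.ndarray, scheme,
                      shrinkage, seed: int) -> float:
    n = arr.shape[0]
    if scheme == "loocv":
        if min((y01 == 0).sum(), (y01 == 1).sum()) < 2:
            raise ValueError("LOOCV needs at least 2 samples per class")
        correct = 0
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            w, b, _ = _fit_core(arr[mask], y01[mask], shrinkage)
            p = float(expit(w @ arr[i] + b))
            correct += int((p > 0.5) == bool(y01[i]))
        return correct / n
    kind = scheme[0]
    if kind != "split":
        raise ValueError(f"unknown CV scheme {scheme!r}")
    _, train_frac, n_rep = scheme
    rng = np.random.default_rng(seed)
    accs = []
    for train, test in _stratified_splits(y01, train_frac, n_rep, rng):
        w, b, _ = _fit_core(arr[train], y01[train], shrinkage)
        p = expit(arr[test] @ w + b)
        accs.append(float(((p > 0.5) == y01[test].astype(bool)).mean()))
    return float(np.mean(accs))


# ---------------------------------------------------------------------------
# genetic algorithm

@dataclass
class GAConfig:
    """Binary-chromosome GA settings.

    ``n_runs`` independent runs are aggregated into selection
    frequencies; each run jitters the per-bit mutation rate uniformly in
    ``mutation_jitter`` (emulating repeated runs under different
    parameter settings).  ``parsimony`` is the subset-size penalty
    lambda: fitness = cv_accuracy - lambda * |S| / n_variables.
    """

    population: int = 50
    generations: int = 100
    crossover_prob: float = 0.8
    mutation_prob: float = 0.1
    elitism_frac: float = 0.05
    parsimony: float = 0.05
    n_runs: int = 40
    mutation_jitter: tuple[float, float] = (0.05, 0.2)
    init_prob: float = 0.3
    stall_restart: int = 15   # reinitialize non-elite after this many
    rng_seed: int = 0         # generations without improvement; 0 = off

    def validate(self) -> None:
        for name in ("crossover_prob", "mutation_prob", "elitism_frac",
                     "init_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} outside [0, 1]")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.population < 2 or self.generations < 1:
            raise ValueError("population >= 2 and generations >= 1 required")


@dataclass
class GASolutionSet:
    """Best-of-run subsets across GA runs plus selection frequencies."""

    solutions: list[tuple[frozenset, float]]     # (variable subset, fitness)
    frequencies: pd.Series                       # per variable, in [0, 1]
    variables: list[str] = field(default_factory=list)

    @property
    def n_runs(self) -> int:
        return len(self.solutions)

    def best(self) -> tuple[frozenset, float]:
        return max(self.solutions, key=lambda sf: sf[1])


def _fitness_factory(arr, y01, scheme, shrinkage, seed, parsimony):
    n_var = arr.shape[1]
    cache: dict[int, float] = {}

    def fitness(mask: np.ndarray) -> float:
        key = np.packbits(mask.astype(np.uint8)).tobytes()
        if key in cache:
            return cache[key]
        if not mask.any():
            val = -np.inf
        else:
            acc = _cv_accuracy_core(arr[:, mask], y01, scheme, shrinkage,
                                    seed)
            val = acc - parsimony * mask.sum() / n_var
        cache[key] = val
        return val

    return fitness


def ga_select(X, labels=None, config: GAConfig | None = None,
              scheme="loocv", shrinkage="auto") -> GASolutionSet:
    """Run the GA feature selection ``config.n_runs`` times.

    Each run: random initial population, tournament selection (size 3),
    uniform crossover, per-bit mutation, elitism; all-zero chromosomes
    are assigned fitness -inf so they are never selected as a best
    solution.  Fully reproducible from ``config.rng_seed``; per-run
    sub-seeds come from a spawned ``SeedSequence``.
    """
    config = config or GAConfig()
    config.validate()
    if isinstance(X, VariableMatrix):
        Xdf, labels = X.labeled()
        arr = Xdf.values.astype(float)
        names = Xdf.columns.tolist()
    elif isinstance(X, pd.DataFrame):
        arr = X.values.astype(float)
        names = X.columns.tolist()
    else:
        arr = np.asarray(X, dtype=float)
        names = [f"v{i}" for i in range(arr.shape[1])]
    y01 = _as_y01(labels)
    n_var = arr.shape[1]
    if n_var < 2:
        raise ValueError("GA needs at least 2 variables")

    fitness = _fitness_factory(arr, y01, scheme, shrinkage,
                               config.rng_seed, config.parsimony)
    root = np.random.SeedSequence(config.rng_seed)
    run_seeds = root.spawn(config.n_runs)
    n_elite = max(1, int(round(config.elitism_frac * config.population)))
    solutions: list[tuple[frozenset, float]] = []

    for ss in run_seeds:
        rng = np.random.default_rng(ss)
        if config.n_runs > 1:
            mut = float(rng.uniform(*config.mutation_jitter))
        else:
            mut = config.mutation_prob
        pop = rng.random((config.population, n_var)) < config.init_prob
        for row in pop:                     # repair all-zero chromosomes
            if not row.any():
                row[rng.integers(n_var)] = True
        fits = np.array([fitness(ind) for ind in pop])
        stall = 0
        run_best = float(fits.max())
        for _ in range(config.generations):
            order = np.argsort(fits)[::-1]
            elite = pop[order[:n_elite]].copy()
            if config.stall_restart and stall >= config.stall_restart:
                # cataclysmic restart: keep the elite, refresh the rest
                fresh = rng.random((config.population - n_elite, n_var)) \
                    < config.init_prob
                for row in fresh:
                    if not row.any():
                        row[rng.integers(n_var)] = True
                pop = np.vstack([elite, fresh])
                fits = np.array([fitness(ind) for ind in pop])
                stall = 0
                order = np.argsort(fits)[::-1]
                elite = pop[order[:n_elite]].copy()
            # tournament selection, size 3
            contenders = rng.integers(0, config.population,
                                      size=(config.population - n_elite, 3))
            winners = contenders[np.arange(len(contenders)),
                                 np.argmax(fits[contenders], axis=1)]
            children = pop[winners].copy()
            # uniform crossover on consecutive pairs
            for i in range(0, len(children) - 1, 2):
                if rng.random() < config.crossover_prob:
                    swap = rng.random(n_var) < 0.5
                    a, b = children[i], children[i + 1]
                    a[swap], b[swap] = b[swap].copy(), a[swap].copy()
            flip = rng.random(children.shape) < mut
            children ^= flip
            pop = np.vstack([elite, children])
            fits = np.array([fitness(ind) for ind in pop])
            new_best = float(fits.max())
            if new_best > run_best + 1e-15:
                run_best, stall = new_best, 0
            else:
                stall += 1
        best_idx = int(np.argmax(fits))
        best = pop[best_idx].copy()
        best_fit = float(fits[best_idx])
        # memetic polish: steepest single-bit-flip ascent from the best
        # chromosome until no flip improves the fitness
        improved = True
        while improved:
            improved = False
            for j in range(n_var):
                cand = best.copy()
                cand[j] = ~cand[j]
                if not cand.any():
                    continue
                f = fitness(cand)
                if f > best_fit + 1e-15:
                    best, best_fit = cand, f
                    improved = True
        subset = frozenset(names[j] for j in np.flatnonzero(best))
        solutions.append((subset, best_fit))

    counts = pd.Series(0.0, index=names)
    for subset, _ in solutions:
        for v in subset:
            counts[v] += 1.0
    freq = counts / config.n_runs
    return GASolutionSet(solutions=solutions, frequencies=freq,
                         variables=names)


# ---------------------------------------------------------------------------
# nested subsets

DEFAULT_CUT_POINTS = (4, 7, 11, 17, None)  # None = all selected variables


@dataclass
class NestedSubsets:
    """Frequency ranking cut into strictly nested variable subsets."""

    ranking: list[str]
    subsets: list[list[str]]

    def __len__(self) -> int:
        return len(self.subsets)


def build_nested_subsets(solutions: GASolutionSet,
                         cut_points=DEFAULT_CUT_POINTS,
                         X=None, labels=None, scheme="loocv",
                         shrinkage="auto", seed: int = 0) -> NestedSubsets:
    """Rank variables by selection frequency and cut into nested subsets.

    Only variables selected at least once enter the ranking.  Frequency
    ties break by descending marginal single-variable cross-validated
    accuracy (when ``X`` is given), then lexicographic variable id; the
    order is therefore deterministic.  Cut points exceeding the number of
    ranked variables are truncated with a warning; ``None`` means "all
    ranked variables".
    """
    freq = solutions.frequencies
    ranked_vars = [v for v in solutions.variables if freq[v] > 0]
    if not ranked_vars:
        raise ValueError("no variable was ever selected by the GA")

    marginal: dict[str, float] = {}
    if X is not None:
        for v in ranked_vars:
            marginal[v] = cv_accuracy(X, labels, subset=[v], scheme=scheme,
                                      shrinkage=shrinkage, seed=seed)
    ranking = sorted(ranked_vars,
                     key=lambda v: (-freq[v], -marginal.get(v, 0.0), v))

    sizes = []
    for cp in cut_points:
        size = len(ranking) if cp is None else int(cp)
        if size > len(ranking):
            warnings.warn(f"cut point {cp} exceeds {len(ranking)} ranked "
                          "variables; truncating")
            size = len(ranking)
        if sizes and size <= sizes[-1]:
            continue  # keep strict nesting
        sizes.append(size)
    subsets = [ranking[:s] for s in sizes]
    return NestedSubsets(ranking=ranking, subsets=subsets)


def evaluate_subsets(X, labels=None, subsets: NestedSubsets | None = None,
                     scheme="loocv", shrinkage="auto",
                     seed: int = 0) -> tuple[pd.DataFrame, int]:
    """Cross-validated accuracy of each nested subset.

    Returns (table, index of the best subset); accuracy ties go to the
    smaller subset (parsimony).
    """
    if subsets is None or not len(subsets):
        raise ValueError("no subsets to evaluate")
    rows = []
    for k, sub in enumerate(subsets.subsets, start=1):
        acc = cv_accuracy(X, labels, subset=sub, scheme=scheme,
                          shrinkage=shrinkage, seed=seed)
        rows.append((k, len(sub), acc))
    table = pd.DataFrame(rows, columns=["subset", "n_variables", "accuracy"])
    best_pos = int(table.sort_values(["accuracy", "n_variables"],
                                     ascending=[False, True],
                                     kind="mergesort").index[0])
    return table, best_pos
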