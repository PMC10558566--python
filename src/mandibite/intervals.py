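"""The adapted Intervals Method for stress-distribution quantification.

The Intervals Method summarizes an FE stress field as the fractions of the
structure's volume falling in each of K stress intervals below a fixed
upper threshold, turning a whole field into a short multivariate profile
that can be ordinated (PCA) across specimens.  The adaptation implemented
here, designed for comparing structures whose stress ranges span an order
of magnitude:

1.  *Trimming*: per simulation, remove the top ``p_trim`` (default 2%) of
    elements by von Mises stress — isolated artifact peaks at constraints.
2.  *Log transform*: work with ln(stress) so highly stressed specimens do
    not dominate the interval layout.
3.  *Scenario threshold*: one upper threshold per biting scenario, the
    volume-weighted (1 - p_tail) quantile (default: 15% of volume above)
    of the pooled log-stress distribution of all specimens in that
    scenario.
4.  *Profiles*: K - 1 uniform intervals between the pooled minimum and the
    threshold plus one open-ended top interval; each element's volume is
    assigned to the interval containing its log stress.
5.  *PCA* on the standardized interval fractions.
6.  *Interval-count selection*: regress PC scores of consecutive candidate
    counts (5, 10, 15, 25, 50); the count at which R² stops increasing is
    retained.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .errors import DegenerateFieldError, ParameterError
from .fem import ElementStressField

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IntervalConfig:
    """Tunable parameters of the adapted Intervals Method."""

    trim_fraction: float = 0.02
    tail_fraction: float = 0.15
    n_intervals: int = 15
    candidate_counts: tuple[int, ...] = (5, 10, 15, 25, 50)
    log_transform: bool = True
    convergence_epsilon: float = 0.01

    def __post_init__(self):
        if not (0 <= self.trim_fraction < 1):
            raise ParameterError("trim_fraction must be in [0, 1)")
        if not (0 < self.tail_fraction < 1):
            raise ParameterError("tail_fraction must be in (0, 1)")
        if self.n_intervals < 2:
            raise ParameterError("n_intervals must be >= 2")
        cc = self.candidate_counts
        if len(cc) < 2 or any(b <= a for a, b in zip(cc, cc[1:])):
            raise ParameterError("candidate_counts must be strictly increasing")
        if self.convergence_epsilon < 0:
            raise ParameterError("convergence_epsilon must be >= 0")


@dataclass
class IntervalProfile:
    """Volume fractions per stress interval for one specimen/scenario."""

    specimen_id: str
    scenario: str
    fractions: np.ndarray

    def __post_init__(self):
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.min() < 0:
            raise ParameterError("interval fractions must be non-negative")
        if abs(self.fractions.sum() - 1.0) > 1e-9:
            raise ParameterError("interval fractions must sum to 1")


# ---------------------------------------------------------------------------
# elementary steps


def trim_top(field: ElementStressField, p_trim: float) -> ElementStressField:
    """Remove the ceil(p_trim * n) highest-stress elements.

    Ties are broken by element id: among equal stresses the higher id is
    removed first.  Remaining volumes are untouched.
    """
    if not (0 <= p_trim < 1):
        raise ParameterError("p_trim must be in [0, 1)")
    n = len(field)
    if n == 0:
        raise DegenerateFieldError("cannot trim an empty stress field")
    k = int(np.ceil(p_trim * n))
    if k == 0:
        return ElementStressField(
            field.element_id.copy(), field.von_mises.copy(),
            field.volume.copy(), is_log=field.is_log,
        )
    order = np.lexsort((field.element_id, field.von_mises))  # ascending
    keep = np.sort(order[: n - k])
    return ElementStressField(
        field.element_id[keep], field.von_mises[keep], field.volume[keep],
        is_log=field.is_log,
    )


def log_stress(field: ElementStressField) -> ElementStressField:
    """Element-wise natural log of stress; volumes unchanged.

    Zero-stress elements (possible next to constraints) are floored to the
    smallest positive stress in the field before the log; their count is
    logged.  An all-zero field is degenerate.
    """
    s = field.von_mises
    pos = s > 0
    if not pos.any():
        raise DegenerateFieldError("all-zero stress field cannot be log-transformed")
    nzero = int((~pos).sum())
    if nzero:
        logger.warning(
            "log_stress: flooring %d zero-stress elements to the field minimum",
            nzero,
        )
        s = np.where(pos, s, s[pos].min())
    return ElementStressField(field.element_id, np.log(s), field.volume,
                              is_log=True)


def weighted_quantile(values, weights, q: float) -> float:
    """Inverted-CDF weighted quantile.

    The smallest value whose cumulative weight fraction reaches ``q``.
    With equal weights over {1..100} and q = 0.85 this is exactly 85.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.size == 0:
        raise ParameterError("empty pool for quantile")
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cum = np.cumsum(w) / w.sum()
    idx = int(np.searchsorted(cum, q, side="left"))
    return float(v[min(idx, len(v) - 1)])


def scenario_threshold(
    fields: list[ElementStressField], p_tail: float
) -> float:
    """Upper interval threshold for one biting scenario.

    The volume-weighted (1 - p_tail) quantile of the pooled (transformed)
    stress distribution of every specimen in the scenario, so that a
    fraction ``p_tail`` of the pooled mandibular volume lies above it.
    """
    if not (0 < p_tail < 1):
        raise ParameterError("p_tail must be in (0, 1)")
    if not fields or sum(len(f) for f in fields) == 0:
        raise ParameterError("empty pool: no elements to set a threshold from")
    values = np.concatenate([f.von_mises for f in fields])
    weights = np.concatenate([f.volume for f in fields])
    return weighted_quantile(values, weights, 1.0 - p_tail)


def pooled_minimum(fields: list[ElementStressField]) -> float:
    """Lower bound of the interval layout: pooled minimum (log-)stress."""
    return float(min(f.von_mises.min() for f in fields))


def interval_profile(
    field: ElementStressField,
    n_intervals: int,
    lower: float,
    threshold: float,
    specimen_id: str = "",
    scenario: str = "",
) -> IntervalProfile:
    """Volume fraction of the structure in each stress interval.

    Intervals 1..K-1 partition [lower, threshold) uniformly; interval K is
    the open-ended [threshold, inf).  Elements below ``lower`` are clamped
    to interval 1 with a logged warning.  Fractions are interval volume
    over total (trimmed) volume and always sum to 1.
    """
    if n_intervals < 2:
        raise ParameterError("n_intervals must be >= 2")
    if not lower < threshold:
        raise ParameterError("lower bound must be below the threshold")
    v = field.von_mises
    below = v < lower
    if below.any():
        logger.warning(
            "interval_profile(%s/%s): clamping %d elements below the lower "
            "bound into interval 1",
            specimen_id,
            scenario,
            int(below.sum()),
        )
    width = (threshold - lower) / (n_intervals - 1)
    idx = np.floor((v - lower) / width).astype(np.int64)
    idx = np.clip(idx, 0, n_intervals - 2)
    idx[v >= threshold] = n_intervals - 1
    volumes = np.bincount(idx, weights=field.volume, minlength=n_intervals)
    return IntervalProfile(
        specimen_id=specimen_id,
        scenario=scenario,
        fractions=volumes / field.volume.sum(),
    )


def scenario_profiles(
    fields: dict[str, ElementStressField],
    config: IntervalConfig,
    scenario: str = "",
    n_intervals: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Full per-scenario pipeline: trim, log, threshold, profiles.

    ``fields`` maps specimen id to its raw solved stress field.  Returns a
    specimens × intervals DataFrame (columns ``interval_1..K``) plus the
    layout (lower bound and threshold actually used).
    """
    K = n_intervals or config.n_intervals
    prepared = {}
    for sid, f in fields.items():
        g = trim_top(f, config.trim_fraction)
        prepared[sid] = log_stress(g) if config.log_transform else g
    thr = scenario_threshold(list(prepared.values()), config.tail_fraction)
    lo = pooled_minimum(list(prepared.values()))
    if not lo < thr:  # degenerate pool (e.g. constant stress everywhere)
        raise DegenerateFieldError(
            "pooled stress distribution is degenerate: lower bound equals "
            "the threshold"
        )
    rows = {
        sid: interval_profile(g, K, lo, thr, sid, scenario).fractions
        for sid, g in prepared.items()
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.columns = [f"interval_{i + 1}" for i in range(K)]
    df.index.name = "specimen_id"
    return df, {"lower": lo, "threshold": thr, "n_intervals": K}


# ---------------------------------------------------------------------------
# ordination and interval-count selection


@dataclass
class PCAResult:
    """PCA of interval profiles (standardized variables)."""

    scores: pd.DataFrame          # specimens × components
    loadings: pd.DataFrame        # intervals × components
    variance_explained: np.ndarray  # percent per component, sums to 100
    dropped_intervals: list[str] = field(default_factory=list)


def pca_profiles(profiles: pd.DataFrame) -> PCAResult:
    """PCA on standardized interval fractions (correlation-matrix PCA).

    Variables are centred and scaled to unit variance, matching the common
    default of multivariate morphometric software; zero-variance intervals
    are dropped with a warning.  Deterministic up to component sign, which
    is fixed by orienting each component to a positive largest loading.
    """
    if len(profiles) < 3:
        raise ParameterError("PCA needs at least 3 specimens")
    if profiles.shape[1] < 2:
        raise ParameterError("PCA needs at least 2 intervals")
    X = profiles.to_numpy(dtype=float)
    sd = X.std(axis=0)
    keep = sd > 0
    dropped = [c for c, k in zip(profiles.columns, keep) if not k]
    if dropped:
        logger.warning("pca_profiles: dropping zero-variance intervals %s", dropped)
    X = X[:, keep]
    Xs = (X - X.mean(axis=0)) / X.std(axis=0)
    n_comp = min(Xs.shape[0] - 1, Xs.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(Xs)
    load = pca.components_.T
    # orient each component so its largest-|.| loading is positive
    for j in range(load.shape[1]):
        i = np.argmax(np.abs(load[:, j]))
        if load[i, j] < 0:
            load[:, j] *= -1
            scores[:, j] *= -1
    var = 100.0 * pca.explained_variance_ratio_
    comp_names = [f"PC{i + 1}" for i in range(n_comp)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=profiles.index, columns=comp_names),
        loadings=pd.DataFrame(
            load,
            index=[c for c, k in zip(profiles.columns, keep) if k],
            columns=comp_names,
        ),
        variance_explained=var,
        dropped_intervals=dropped,
    )


@dataclass
class ConvergenceResult:
    """Interval-count convergence over the candidate ladder."""

    candidate_counts: tuple[int, ...]
    r_squared_pc1: list[float]
    r_squared_pc2: list[float]
    chosen_k: int
    converged: bool

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)


def _r_squared(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation — the R² of the simple regression a~b,
    invariant to the sign ambiguity of PC scores."""
    if np.std(a) == 0 or np.std(b) == 0:
        return 1.0 if np.std(a) == np.std(b) else 0.0
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def choose_interval_count(
    candidate_counts: tuple[int, ...],
    r_squared: list[float],
    epsilon: float,
) -> tuple[int, bool]:
    """Decision rule on a ladder of consecutive-count R² values.

    ``r_squared[i]`` relates candidate i to candidate i+1.  The chosen
    count is ``candidate_counts[i]`` for the smallest i at which the next
    R² no longer exceeds the current one by more than ``epsilon`` (the
    gain from refining past i has saturated).  Identical score vectors
    throughout (all R² = 1) therefore select the first candidate.  A
    monotonically increasing sequence returns the largest candidate,
    flagged not converged.
    """
    if len(r_squared) != len(candidate_counts) - 1:
        raise ParameterError("need one R² per consecutive candidate pair")
    for i in range(len(r_squared) - 1):
        if r_squared[i + 1] <= r_squared[i] + epsilon:
            return candidate_counts[i], True
    return candidate_counts[-1], False


def select_interval_count(
    fields: dict[str, ElementStressField],
    config: IntervalConfig,
    scenario: str = "",
) -> ConvergenceResult:
    """Choose the interval count by convergence of PC scores.

    For consecutive candidate counts k, k' the R² between their PC1 (and
    PC2) score vectors is recorded.  The chosen count is the first
    candidate after which the PC1 R² stops increasing by more than
    ``convergence_epsilon``; if R² increases monotonically through the
    whole ladder the largest candidate is returned flagged non-converged.
    """
    counts = config.candidate_counts
    pcas = []
    for k in counts:
        df, _ = scenario_profiles(fields, config, scenario, n_intervals=k)
        pcas.append(pca_profiles(df))
    r1 = [
        _r_squared(
            pcas[i].scores["PC1"].to_numpy(), pcas[i + 1].scores["PC1"].to_numpy()
        )
        for i in range(len(counts) - 1)
    ]
    r2 = [
        _r_squared(
            pcas[i].scores["PC2"].to_numpy(), pcas[i + 1].scores["PC2"].to_numpy()
        )
        if "PC2" in pcas[i].scores and "PC2" in pcas[i + 1].scores
        else float("nan")
        for i in range(len(counts) - 1)
    ]
    chosen, converged = choose_interval_count(
        counts, r1, config.convergence_epsilon
    )
    return ConvergenceResult(counts, r1, r2, chosen, converged)


def read_intervals_table(path) -> pd.DataFrame:
    """Read a precomputed specimens × intervals CSV straight into PCA.

    First column (or an explicit ``specimen_id`` column) indexes specimens;
    remaining columns are interval fractions or percentages (percentages
    are rescaled to fractions).
    """
    df = pd.read_csv(path)
    first = df.columns[0]
    idcol = "specimen_id" if "specimen_id" in df.columns else first
    df = df.set_index(idcol)
    df = df.apply(pd.to_numeric)
    rowsum = df.sum(axis=1)
    if np.allclose(rowsum, 100.0, rtol=0.05):
        df = df / 100.0
    return df
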