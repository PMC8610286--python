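"""Mutation-score survival stratification.

For each candidate gene a univariate Cox proportional-hazards fit on the
gene's mutation indicator yields a hazard ratio (HR) and p-value; genes
significant at ``alpha`` receive a sign w = +1 (HR >= 1, risk) or -1
(HR < 1, protective).  Each patient's mutation score is then

    MS = sum_j w_j * M_j

over the retained genes, with M_j the 0/1 mutation indicator.  Patients
are split into high-MS (MS > cutoff) and low-MS groups at either the
median MS or the cutoff minimising the log-rank p-value, and the two
survival curves are compared by the standard two-sample log-rank test.

Follow-up is conventionally right-truncated at a 10-year horizon
(3652 days) before any fit, via :func:`truncate_followup`.

The proportional-hazards estimator and the log-rank statistic are the
standard ones (lifelines); this module owns only the scoring and
stratification logic around them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test

#: 10-year follow-up horizon, in days.
TEN_YEARS_DAYS = 3652


@dataclass
class SurvivalCohort:
    """Per-patient follow-up, event indicator, and gene mutation indicators.

    ``data`` columns: ``patient``, ``time_days``, ``event`` (1 death,
    0 censored), then one 0/1 column per gene.
    """

    data: pd.DataFrame

    RESERVED = ("patient", "time_days", "event")

    def __post_init__(self) -> None:
        for col in self.RESERVED:
            if col not in self.data.columns:
                raise ValueError(f"survival table missing column {col!r}")
        if (self.data["time_days"] <= 0).any():
            raise ValueError("follow-up times must be positive")
        if not self.data["event"].isin([0, 1]).all():
            raise ValueError("event indicators must be 0/1")
        for g in self.genes:
            if not self.data[g].isin([0, 1]).all():
                raise ValueError(f"mutation indicators for {g!r} must be 0/1")

    @property
    def genes(self) -> list[str]:
        return [c for c in self.data.columns if c not in self.RESERVED]

    @property
    def n_patients(self) -> int:
        return len(self.data)


def load_survival(path) -> SurvivalCohort:
    df = pd.read_csv(path, sep="\t")
    return SurvivalCohort(df)


def write_survival(cohort: SurvivalCohort, path) -> None:
    cohort.data.to_csv(path, sep="\t", index=False)


def truncate_followup(
    cohort: SurvivalCohort, horizon_days: int = TEN_YEARS_DAYS
) -> SurvivalCohort:
    """Right-truncate follow-up at the horizon: later times are clamped and
    their events censored (the analysis then concerns horizon-limited
    survival only)."""
    df = cohort.data.copy()
    over = df["time_days"] > horizon_days
    df.loc[over, "event"] = 0
    df.loc[over, "time_days"] = horizon_days
    return SurvivalCohort(df)


# ---------------------------------------------------------------------------
# per-gene screen


@dataclass
class GeneWeight:
    gene: str
    hr: float
    p_value: float
    w: int  # +1 for HR >= 1, -1 for HR < 1

    def __post_init__(self) -> None:
        expected = 1 if self.hr >= 1.0 else -1
        if self.w != expected:
            raise ValueError(f"weight {self.w} inconsistent with HR {self.hr}")


def per_gene_weights(
    cohort: SurvivalCohort,
    genes: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> list[GeneWeight]:
    """Univariate proportional-hazards screen over ``genes``.

    Genes mutated in no patient or in every patient, and fits that fail to
    converge (separation), are skipped with a warning.  Only genes with
    p < alpha are returned, signed by the HR rule.
    """
    if genes is None:
        genes = cohort.genes
    out: list[GeneWeight] = []
    for gene in genes:
        if gene not in cohort.data.columns:
            raise KeyError(f"gene {gene!r} absent from cohort")
        m = cohort.data[gene]
        if m.nunique() < 2:
            warnings.warn(
                f"gene {gene}: mutation indicator constant, skipped",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        df = cohort.data[["time_days", "event", gene]]
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="time_days", event_col="event")
        except (ConvergenceError, np.linalg.LinAlgError) as exc:
            warnings.warn(
                f"gene {gene}: proportional-hazards fit failed ({exc}), skipped",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        hr = float(np.exp(cph.params_[gene]))
        p = float(cph.summary.loc[gene, "p"])
        if p < alpha:
            out.append(GeneWeight(gene=gene, hr=hr, p_value=p, w=1 if hr >= 1 else -1))
    return out


# ---------------------------------------------------------------------------
# mutation score and stratification


def mutation_score(patient_row: Mapping[str, int], weights: Sequence[GeneWeight]) -> int:
    """MS = sum_j w_j * M_j over the retained genes."""
    if not weights:
        raise ValueError("mutation_score needs at least one gene weight")
    return int(sum(gw.w * int(patient_row[gw.gene]) for gw in weights))


def mutation_scores(cohort: SurvivalCohort, weights: Sequence[GeneWeight]) -> np.ndarray:
    if not weights:
        raise ValueError("mutation_scores needs at least one gene weight")
    ms = np.zeros(cohort.n_patients, dtype=int)
    for gw in weights:
        ms += gw.w * cohort.data[gw.gene].to_numpy(dtype=int)
    return ms


@dataclass
class LogrankResult:
    statistic: float
    p_value: float
    #: True when a group had zero events (statistic still computed)
    zero_event_group: bool = False


@dataclass
class MSSplit:
    """High/low mutation-score stratification of a cohort."""

    groups: np.ndarray  # "high" / "low" per patient, cohort order
    cutoff: float
    strategy: str
    logrank: LogrankResult
    #: best-cutoff p-values are minima over candidates: selection-biased
    selection_biased: bool = False


def logrank(groups: Sequence[str] | np.ndarray, cohort: SurvivalCohort) -> LogrankResult:
    """Two-sample log-rank test between the "high" and "low" groups."""
    groups = np.asarray(groups)
    hi = groups == "high"
    lo = groups == "low"
    if not hi.any() or not lo.any():
        raise ValueError("both groups must be nonempty")
    t = cohort.data["time_days"].to_numpy(dtype=float)
    e = cohort.data["event"].to_numpy(dtype=int)
    res = logrank_test(t[hi], t[lo], event_observed_A=e[hi], event_observed_B=e[lo])
    zero = e[hi].sum() == 0 or e[lo].sum() == 0
    if zero:
        warnings.warn("a group has zero events", RuntimeWarning, stacklevel=2)
    return LogrankResult(
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        zero_event_group=bool(zero),
    )


def split_groups(
    ms: np.ndarray,
    cohort: SurvivalCohort,
    strategy: str = "median",
) -> MSSplit:
    """Assign each patient to high (MS > cutoff) or low (MS <= cutoff).

    ``median`` uses the median MS; ``best`` scans candidate cutoffs between
    the 10th and 90th MS percentiles and keeps the one minimising the
    log-rank p-value (reported as selection-biased, no correction applied).
    """
    ms = np.asarray(ms)
    if len(ms) != cohort.n_patients:
        raise ValueError("MS vector length differs from cohort size")
    if np.unique(ms).size < 2:
        raise ValueError("constant mutation score: no split possible")

    def assign(cutoff: float) -> np.ndarray:
        return np.where(ms > cutoff, "high", "low")

    if strategy == "median":
        cutoff = float(np.median(ms))
        groups = assign(cutoff)
        if len(set(groups)) < 2:
            # median sits at the maximum; fall back to the largest cutoff
            # that still leaves both sides populated
            cutoff = float(np.max(ms[ms < np.max(ms)]))
            groups = assign(cutoff)
        lr = logrank(groups, cohort)
        return MSSplit(groups=groups, cutoff=cutoff, strategy="median", logrank=lr)
    if strategy == "best":
        lo_q, hi_q = np.percentile(ms, [10, 90])
        candidates = [c for c in np.unique(ms) if lo_q <= c <= hi_q]
        candidates = [c for c in candidates if (ms > c).any() and (ms <= c).any()]
        if not candidates:
            raise ValueError("no valid cutoff candidates between the 10th and 90th percentiles")
        best_split: MSSplit | None = None
        for c in candidates:
            groups = assign(float(c))
            lr = logrank(groups, cohort)
            if best_split is None or lr.p_value < best_split.logrank.p_value:
                best_split = MSSplit(
                    groups=groups,
                    cutoff=float(c),
                    strategy="best",
                    logrank=lr,
                    selection_biased=True,
                )
        return best_split
    raise ValueError(f"unknown strategy {strategy!r}")


def km_coordinates(groups: Sequence[str], cohort: SurvivalCohort) -> pd.DataFrame:
    """Kaplan-Meier survival-curve coordinates per group, for plotting."""
    from lifelines import KaplanMeierFitter

    groups = np.asarray(groups)
    frames = []
    for name in ("high", "low"):
        sel = groups == name
        if not sel.any():
            continue
        km = KaplanMeierFitter()
        km.fit(
            cohort.data.loc[sel, "time_days"],
            cohort.data.loc[sel, "event"],
            label=name,
        )
        df = km.survival_function_.reset_index()
        df.columns = ["time_days", "survival"]
        df.insert(0, "group", name)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
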