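"""Taguchi L16(4^3) orthogonal design and factor-effect analysis.

The three feature-extraction hyperparameters — window size, sliding
step, preFOG label duration — each take four levels.  The full
factorial has 64 runs; the strength-2 orthogonal array L16(4^3) covers
every pairwise level combination exactly once in 16 runs, so main
effects (and, with numeric coding, one two-factor interaction) can be
screened at a quarter of the cost.  Term significance is reported on
the LogWorth scale, -log10(p); LogWorth above 2 means p < 0.01.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .features import concat_matrices, extract_matrix
from .model import pooled_metrics, train_and_eval, RFParams
from .preprocess import SegmentationParams, segment_and_label
from .synth import EventAnnotation, IMURecording

__all__ = [
    "FactorSpec",
    "DesignTable",
    "ResponseTable",
    "EffectSummary",
    "default_factors",
    "build_l16_4_3",
    "verify_orthogonality",
    "full_factorial",
    "run_design",
    "effects_analysis",
    "select_best",
]

logger = logging.getLogger(__name__)

FACTOR_NAMES = ("window_size", "step", "prefog_duration")

#: Level-index matrix of the L16(4^3) array (rows T01..T16, 0-based levels).
L16_4_3 = np.array(
    [
        [0, 0, 0], [0, 1, 1], [0, 2, 2], [0, 3, 3],
        [1, 0, 1], [1, 1, 0], [1, 2, 3], [1, 3, 2],
        [2, 0, 2], [2, 1, 3], [2, 2, 0], [2, 3, 1],
        [3, 0, 3], [3, 1, 2], [3, 2, 1], [3, 3, 0],
    ]
)


@dataclass(frozen=True)
class FactorSpec:
    name: str
    levels: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if self.name not in FACTOR_NAMES:
            raise ValueError(f"unknown factor {self.name!r}")
        if len(set(self.levels)) != 4:
            raise ValueError("each factor needs exactly 4 distinct levels")
        if list(self.levels) != sorted(self.levels) or min(self.levels) <= 0:
            raise ValueError("levels must be increasing positive integers")


def default_factors() -> list[FactorSpec]:
    """The studied level sets for the three windowing hyperparameters."""
    return [
        FactorSpec("window_size", (128, 256, 400, 500)),
        FactorSpec("step", (5, 10, 20, 30)),
        FactorSpec("prefog_duration", (150, 250, 500, 600)),
    ]


@dataclass
class DesignTable:
    runs: pd.DataFrame  # columns: run_id + factor names
    design_name: str

    def __len__(self) -> int:
        return len(self.runs)

    def to_csv(self, path) -> None:
        self.runs.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, design_name: str = "custom") -> "DesignTable":
        return cls(pd.read_csv(path), design_name)


def build_l16_4_3(factors: list[FactorSpec]) -> DesignTable:
    """The 16-run strength-2 orthogonal array over three 4-level factors."""
    if len(factors) != 3:
        raise ValueError("L16(4^3) takes exactly 3 factors")
    names = [f.name for f in factors]
    if names != list(FACTOR_NAMES):
        raise ValueError(f"factors must be ordered {FACTOR_NAMES}")
    rows = {
        "run_id": [f"T{i + 1:02d}" for i in range(16)],
    }
    for j, f in enumerate(factors):
        rows[f.name] = [f.levels[k] for k in L16_4_3[:, j]]
    return DesignTable(pd.DataFrame(rows), "L16(4^3)")


def full_factorial(factors: list[FactorSpec]) -> DesignTable:
    """Cartesian product of all levels, lexicographic order."""
    if not factors:
        raise ValueError("need at least one factor")
    combos = list(itertools.product(*(f.levels for f in factors)))
    rows = {"run_id": [f"R{i + 1:02d}" for i in range(len(combos))]}
    for j, f in enumerate(factors):
        rows[f.name] = [c[j] for c in combos]
    return DesignTable(pd.DataFrame(rows), "full-factorial")


@dataclass
class BalanceReport:
    level_balance: dict[str, bool]
    pair_balance: dict[tuple[str, str], bool]
    pair_frequency: dict[tuple[str, str], int | None]
    failures: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.failures


def verify_orthogonality(d: DesignTable) -> BalanceReport:
    """Check strength-2 orthogonal-array balance.

    (a) every level of every factor appears runs/4 times; (b) for each
    factor pair, all 16 ordered level combinations occur with equal
    frequency (exactly once for the L16 array, four times for the full
    4^3 factorial).
    """
    factors = [c for c in d.runs.columns if c != "run_id"]
    n = len(d.runs)
    level_balance: dict[str, bool] = {}
    failures: list[str] = []
    for f in factors:
        counts = d.runs[f].value_counts()
        ok = len(counts) == 4 and counts.nunique() == 1 and counts.iloc[0] == n // 4
        level_balance[f] = bool(ok)
        if not ok:
            failures.append(f"factor {f}: unequal level frequencies")
    pair_balance: dict[tuple[str, str], bool] = {}
    pair_frequency: dict[tuple[str, str], int | None] = {}
    for a, b in itertools.combinations(factors, 2):
        counts = d.runs.groupby([a, b]).size()
        ok = len(counts) == 16 and counts.nunique() == 1
        pair_balance[(a, b)] = bool(ok)
        pair_frequency[(a, b)] = int(counts.iloc[0]) if ok else None
        if not ok:
            failures.append(f"factor pair ({a}, {b}): unbalanced level combinations")
    return BalanceReport(level_balance, pair_balance, pair_frequency, failures)


@dataclass
class ResponseTable:
    rows: pd.DataFrame  # run_id, factors, replicate, f1, kappa, n_prefog, n_windows

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ResponseTable":
        return cls(pd.read_csv(path))


def run_design(
    d: DesignTable,
    data: list[tuple[IMURecording, EventAnnotation]],
    rf_params: RFParams,
    seeds: list[int] | None = None,
) -> ResponseTable:
    """Execute the pipeline once per design run (per replicate seed).

    The recordings are assumed already cleaned (outlier replacement and
    detrending are windowing-independent, so the caller does them once).
    Each run segments and labels with its own (window, step, preFOG
    duration), extracts features, and scores the forest under
    leave-one-patient-out CV with pooled window-level F1 and kappa.
    Runs that yield no prefog windows are recorded with missing metrics.
    """
    if len({rec.patient_id for rec, _ in data}) < 2:
        raise ValueError("run_design needs >= 2 patients")
    seeds = list(seeds) if seeds is not None else [rf_params.seed]
    out = []
    for _, run in d.runs.iterrows():
        p = SegmentationParams(
            int(run["window_size"]), int(run["step"]), int(run["prefog_duration"])
        )
        mats = [
            extract_matrix(segment_and_label(rec, ann, p)) for rec, ann in data
        ]
        fm = concat_matrices(mats)
        n_prefog = int((fm.labels == "prefog").sum())
        for rep, seed in enumerate(seeds):
            row = {
                "run_id": run["run_id"],
                **{f: int(run[f]) for f in FACTOR_NAMES},
                "replicate": rep,
                "n_windows": len(fm.features),
                "n_prefog": n_prefog,
            }
            if n_prefog == 0 or n_prefog == len(fm.features):
                logger.warning(
                    "run %s: degenerate labels (%d prefog of %d windows); "
                    "metrics recorded as missing",
                    run["run_id"], n_prefog, len(fm.features),
                )
                row["f1"] = np.nan
                row["kappa"] = np.nan
            else:
                from dataclasses import replace
                folds = train_and_eval(fm, replace(rf_params, seed=seed))
                f1, kap = pooled_metrics(folds)
                row["f1"] = f1
                row["kappa"] = kap
            out.append(row)
    return ResponseTable(pd.DataFrame(out))


@dataclass
class EffectSummary:
    terms: pd.DataFrame  # term, p_value, logworth, estimate
    level_means: dict[str, pd.Series]  # factor -> mean response per level
    response: str
    coding: str

    def logworth(self, term: str) -> float:
        row = self.terms.loc[self.terms["term"] == term]
        if row.empty:
            raise KeyError(term)
        return float(row["logworth"].iloc[0])


def _parse_interactions(interactions) -> list[tuple[str, str]]:
    pairs = []
    for item in interactions or []:
        pair = tuple(item.split(":")) if isinstance(item, str) else tuple(item)
        if len(pair) != 2:
            raise ValueError(
                "only two-factor interactions are supported; higher-order "
                "interactions are assumed to be non-existent"
            )
        for f in pair:
            if f not in FACTOR_NAMES:
                raise ValueError(f"unknown factor {f!r} in interaction")
        pairs.append(pair)  # type: ignore[arg-type]
    return pairs


def effects_analysis(
    d: DesignTable,
    r: ResponseTable,
    response: str = "f1",
    interactions: list | None = None,
    coding: str = "auto",
) -> EffectSummary:
    """Fit a linear model of the response on factor terms; report LogWorth.

    Two codings are available.  ``numeric`` centers each factor's level
    values and fits linear main effects plus product terms for the
    requested interactions — the only option that leaves residual
    degrees of freedom on a single-replicate 16-run table.  ``categorical``
    fits a type-II ANOVA with 4-level factors, usable when replicates
    provide residual df.  ``auto`` picks categorical when it leaves
    at least one residual df, else numeric.
    """
    if response not in ("f1", "kappa"):
        raise ValueError("response must be 'f1' or 'kappa'")
    pairs = _parse_interactions(interactions)
    df = r.rows.dropna(subset=[response]).copy()
    if len(df) < len(r.rows):
        logger.warning(
            "%d run(s) with missing %s excluded from the effect fit",
            len(r.rows) - len(df), response,
        )
    if df.empty:
        raise ValueError("no usable responses")

    # Per-level response means for main-effect plots/selection.
    level_means = {
        f: df.groupby(f)[response].mean() for f in FACTOR_NAMES
    }

    if np.ptp(df[response].to_numpy()) == 0:
        # perfectly flat response: no effect evidence at all
        names = list(FACTOR_NAMES) + [f"{a}*{b}" for a, b in pairs]
        terms_df = pd.DataFrame(
            {"term": names, "p_value": 1.0, "estimate": 0.0, "logworth": 0.0}
        )
        return EffectSummary(terms_df, level_means, response, "null")

    if coding == "auto":
        n_params_cat = 1 + 3 * 3 + sum(9 for _ in pairs)
        coding = "categorical" if len(df) > n_params_cat else "numeric"

    if coding == "numeric":
        work = df.copy()
        for f in FACTOR_NAMES:
            work[f"{f}_c"] = work[f] - work[f].mean()
        terms = [f"{f}_c" for f in FACTOR_NAMES]
        for a, b in pairs:
            work[f"{a}_x_{b}"] = work[f"{a}_c"] * work[f"{b}_c"]
            terms.append(f"{a}_x_{b}")
        X = sm.add_constant(work[terms])
        fit = sm.OLS(work[response], X).fit()
        rows = []
        for t in terms:
            name = t.replace("_c", "").replace("_x_", "*")
            p = float(fit.pvalues[t])
            rows.append(
                {
                    "term": name,
                    "p_value": min(max(p, np.finfo(float).tiny), 1.0) if np.isfinite(p) else 1.0,
                    "estimate": float(fit.params[t]),
                }
            )
    elif coding == "categorical":
        formula = " + ".join(f"C({f})" for f in FACTOR_NAMES)
        for a, b in pairs:
            formula += f" + C({a}):C({b})"
        fit = smf.ols(f"{response} ~ {formula}", data=df).fit()
        anova = sm.stats.anova_lm(fit, typ=2)
        rows = []
        for term, row in anova.iterrows():
            if term == "Residual":
                continue
            name = (
                term.replace("C(", "").replace(")", "").replace(":", "*")
            )
            p = float(row["PR(>F)"])
            rows.append(
                {
                    "term": name,
                    "p_value": min(max(p, np.finfo(float).tiny), 1.0) if np.isfinite(p) else 1.0,
                    "estimate": float(row["sum_sq"]),
                }
            )
    else:
        raise ValueError("coding must be 'auto', 'numeric' or 'categorical'")

    terms_df = pd.DataFrame(rows)
    terms_df["logworth"] = -np.log10(terms_df["p_value"])
    return EffectSummary(terms_df, level_means, response, coding)


def select_best(e: EffectSummary) -> SegmentationParams:
    """Pick, per factor, the level maximizing the mean response.

    Near-equal means (within 1e-9) are tied; ties resolve toward the
    cheaper, more causal setting: smaller window, larger step, smaller
    preFOG duration.
    """
    chosen: dict[str, int] = {}
    prefer_small = {"window_size": True, "step": False, "prefog_duration": True}
    for f in FACTOR_NAMES:
        means = e.level_means.get(f)
        if means is None or means.isna().any() or len(means) != 4:
            raise ValueError(f"missing level means for factor {f}")
        best_val = means.max()
        tied = sorted(means.index[means >= best_val - 1e-9])
        chosen[f] = int(tied[0] if prefer_small[f] else tied[-1])
    return SegmentationParams(
        chosen["window_size"], chosen["step"], chosen["prefog_duration"]
    )
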