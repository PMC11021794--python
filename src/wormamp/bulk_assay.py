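"""Miles-Misra colony-count analysis.

The drop-plate (Miles & Misra) assay enumerates viable bacteria: a 10 uL
aliquot of each well is serially diluted, spotted on agar, and colonies are
counted on the least-diluted plate giving distinct colonies.  CFU/mL is
back-calculated as

    CFU/mL = colonies x 20 x dilution_factor x 5

(20 converts the 10 uL aliquot to per-mL under the assay's 1:10 spotting
convention, 5 the pre-plating step).  Conditions are compared by one-way
ANOVA with Tukey's HSD on per-replicate CFU/mL values.

An end-to-end in-silico version of the assay (inoculum -> exponential
birth-death growth -> Poisson colony sampling -> the CFU formula) is
provided to cross-validate the population model against the formula-based
readout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .population_model import PopulationParams, predict_ratio

__all__ = [
    "PlateCount", "AssayConfig", "cfu_per_ml", "inoculum_cfu",
    "percent_reduction", "select_countable", "anova_tukey", "AnovaReport",
    "simulate_assay",
]

DEFAULT_DILUTIONS = (10, 100, 1000)


@dataclass(frozen=True)
class PlateCount:
    condition: str
    replicate: int
    dilution_factor: int
    colonies: int

    def __post_init__(self) -> None:
        if self.colonies < 0:
            raise ValueError("colonies must be non-negative")


@dataclass(frozen=True)
class AssayConfig:
    """Protocol constants of the bulk killing assay."""

    od600: float = 0.165
    od_cfu_per_ml: float = 1.5e8      # culture density at od600
    predilution: float = 5000.0       # 1:5000 before inoculation
    aliquot_ul: float = 10.0          # volume added to each well
    well_volume_ul: float = 200.0
    peptide_conc_ug_ml: float = 100.0
    incubation_min: float = 210.0
    alpha_level: float = 0.05
    dilution_ladder: tuple[int, ...] = DEFAULT_DILUTIONS
    countable_band: tuple[int, int] = (3, 300)

    def __post_init__(self) -> None:
        for name in ("od600", "predilution", "aliquot_ul",
                     "well_volume_ul", "peptide_conc_ug_ml", "incubation_min",
                     "alpha_level"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.od_cfu_per_ml < 0:  # zero models a sterile culture
            raise ValueError("od_cfu_per_ml must be non-negative")


def cfu_per_ml(count: PlateCount, config: AssayConfig | None = None) -> float:
    """Colonies x 20 x dilution factor x 5."""
    cfg = config or AssayConfig()
    if count.dilution_factor not in cfg.dilution_ladder:
        raise ValueError(
            f"dilution factor {count.dilution_factor} not in ladder {cfg.dilution_ladder}")
    return float(count.colonies) * 20.0 * count.dilution_factor * 5.0


def inoculum_cfu(config: AssayConfig | None = None) -> dict:
    """Initial bacterial load of a well, from the printed protocol.

    With defaults: 1.5e8 / 5000 = 3.0e4 CFU/mL in the prediluted culture;
    10 uL -> 300 CFU per well; in 200 uL -> 1.5e3 CFU/mL in the well.
    """
    cfg = config or AssayConfig()
    density = cfg.od_cfu_per_ml / cfg.predilution
    per_well = density * cfg.aliquot_ul / 1000.0
    return {
        "prediluted_cfu_per_ml": density,
        "cfu_per_well": per_well,
        "well_cfu_per_ml": per_well / (cfg.well_volume_ul / 1000.0),
    }


def percent_reduction(treated_cfu_ml: float, control_cfu_ml: float) -> float:
    """100 * (1 - treated/control); 100 means complete elimination."""
    if control_cfu_ml <= 0:
        raise ValueError("control CFU/mL must be positive")
    return 100.0 * (1.0 - treated_cfu_ml / control_cfu_ml)


def select_countable(counts: list[PlateCount], config: AssayConfig | None = None,
                     ) -> PlateCount:
    """The least-diluted plate yielding distinct colonies: smallest dilution
    whose count falls in the countable band; falls back to the least diluted
    non-overgrown plate, then to the most diluted plate."""
    cfg = config or AssayConfig()
    lo, hi = cfg.countable_band
    ordered = sorted(counts, key=lambda c: c.dilution_factor)
    for c in ordered:
        if lo <= c.colonies <= hi:
            return c
    for c in ordered:
        if c.colonies <= hi:
            return c
    return ordered[-1]


@dataclass
class AnovaReport:
    f_statistic: float
    p_value: float
    pairwise: pd.DataFrame     # group1, group2, meandiff, p_adj, reject
    alpha_level: float
    log_transformed: bool = False
    note: str = ""

    def significant_pairs(self) -> list[tuple[str, str]]:
        return [(r.group1, r.group2) for r in self.pairwise.itertuples(index=False)
                if r.reject]


def anova_tukey(groups: dict[str, list[float]], alpha_level: float = 0.05,
                log_transform: bool = False) -> AnovaReport:
    """One-way ANOVA with Tukey HSD pairwise comparisons on replicate CFU/mL.

    ``groups`` maps condition labels to replicate values.  With
    ``log_transform`` the test runs on log10(x + 1) (counts can be zero when
    a peptide eliminates all colonies).  Degenerate input (zero variance
    within every group and equal means) is reported with F = 0 and a note
    rather than NaN propagation.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for label, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {label!r} needs >= 2 replicates")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if log_transform:
        arrays = {k: np.log10(v + 1.0) for k, v in arrays.items()}
    values = np.concatenate(list(arrays.values()))
    labels = np.concatenate([[k] * len(v) for k, v in arrays.items()])

    within_var = sum(float(v.var(ddof=1)) for v in arrays.values())
    if within_var == 0:
        means = {k: v.mean() for k, v in arrays.items()}
        if len(set(means.values())) == 1:
            pairs = []
            ks = list(arrays)
            for i, g1 in enumerate(ks):
                for g2 in ks[i + 1:]:
                    pairs.append((g1, g2, 0.0, 1.0, False))
            return AnovaReport(0.0, 1.0,
                               pd.DataFrame(pairs, columns=["group1", "group2",
                                                            "meandiff", "p_adj",
                                                            "reject"]),
                               alpha_level, log_transform,
                               note="degenerate: zero variance within all groups")
        # zero within-group variance but different means: infinite evidence
        raise ValueError(
            "degenerate input: zero within-group variance with unequal group "
            "means; ANOVA F is unbounded — add replicates or jitter")

    f_stat, p_val = stats.f_oneway(*arrays.values())
    tk = pairwise_tukeyhsd(values, labels, alpha=alpha_level)
    g1, g2 = zip(*((tk.groupsunique[i], tk.groupsunique[j])
                   for i, j in zip(*np.triu_indices(len(tk.groupsunique), 1))))
    pairwise = pd.DataFrame({
        "group1": g1, "group2": g2,
        "meandiff": np.asarray(tk.meandiffs, dtype=float),
        "p_adj": np.asarray(tk.pvalues, dtype=float),
        "reject": np.asarray(tk.reject, dtype=bool),
    })
    return AnovaReport(float(f_stat), float(p_val), pairwise, alpha_level,
                       log_transform)


def analyze_counts(counts: pd.DataFrame, config: AssayConfig | None = None,
                   control: str = "control", log_transform: bool = False,
                   ) -> dict:
    """Full bulk-assay analysis from a plate-count table.

    ``counts`` columns: condition, replicate, dilution_factor, colonies.
    For each condition x replicate the countable plate is selected, CFU/mL
    computed, percent reductions taken against the control condition's mean,
    and ANOVA + Tukey run across conditions.
    """
    cfg = config or AssayConfig()
    rows = []
    for (cond, rep), g in counts.groupby(["condition", "replicate"]):
        pcs = [PlateCount(cond, rep, int(r.dilution_factor), int(r.colonies))
               for r in g.itertuples(index=False)]
        chosen = select_countable(pcs, cfg)
        rows.append((cond, rep, chosen.dilution_factor, chosen.colonies,
                     cfu_per_ml(chosen, cfg)))
    cfu = pd.DataFrame(rows, columns=["condition", "replicate",
                                      "dilution_factor", "colonies", "cfu_per_ml"])
    if control not in set(cfu["condition"]):
        raise ValueError(f"control condition {control!r} not present")
    ctrl_mean = cfu.loc[cfu["condition"] == control, "cfu_per_ml"].mean()
    summary = (cfu.groupby("condition")["cfu_per_ml"]
               .agg(["mean", "std", "count"]).reset_index())
    summary["reduction_pct"] = [percent_reduction(m, ctrl_mean)
                                for m in summary["mean"]]
    groups = {c: g["cfu_per_ml"].tolist() for c, g in cfu.groupby("condition")}
    report = anova_tukey(groups, cfg.alpha_level, log_transform)
    return {"cfu": cfu, "summary": summary, "anova": report}


def simulate_assay(pop: PopulationParams, rng: np.random.Generator,
                   config: AssayConfig | None = None, n_replicates: int = 3,
                   ) -> pd.DataFrame:
    """In-silico Miles-Misra run: grow the inoculum under the birth-death
    model, Poisson-sample colonies on each dilution plate, apply the CFU
    formula.  Returns a plate-count table (conditions ``control`` and
    ``treated``) suitable for :func:`analyze_counts`.
    """
    cfg = config or AssayConfig()
    n0 = inoculum_cfu(cfg)["well_cfu_per_ml"]
    growth_c = math.exp((pop.alpha_control - pop.lambda_control) * pop.duration_min)
    final = {"control": n0 * growth_c,
             "treated": n0 * growth_c * predict_ratio(pop)}
    rows = []
    for cond, density in final.items():
        for rep in range(1, n_replicates + 1):
            for dil in cfg.dilution_ladder:
                # exact inverse of the CFU formula: colonies = CFU/mL / (100 dil)
                mean_colonies = density / (20.0 * 5.0) / dil
                n = int(rng.poisson(mean_colonies))
                rows.append((cond, rep, dil, n))
    return pd.DataFrame(rows, columns=["condition", "replicate",
                                       "dilution_factor", "colonies"])
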