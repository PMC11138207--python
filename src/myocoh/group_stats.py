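"""Pre/post group statistics: paired t-tests, Pearson correlations with
Benjamini-Hochberg FDR control, SIS domain construction, and the combined
group report.

All tests are two-sided. Paired tests on distinct outcome domains are
treated as independent (no cross-domain correction); correlation matrices
are BH-adjusted within one declared family (by default, all cells of one
matrix at one timepoint), and the family membership is recorded in the
output so the correction is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateError, ParameterError
from .synthetic_data import ClinicalTable


@dataclass
class StatResult:
    kind: str  # 'paired_t' | 'pearson'
    statistic: float
    df: int
    p_two_sided: float
    estimate: float  # mean difference or correlation coefficient
    n: int
    p_adjusted: float | None = None
    family: str | None = None


@dataclass
class SISDomainScores:
    """ICF-aligned domains on the 0-100 normalized SIS scale."""

    impairment: float
    function: float
    participation: float


#: items per SIS subscale (version 3.0), used to normalize raw sums
SIS_ITEM_COUNTS = {
    "Strength": 4,
    "ADL": 10,
    "Hand Function": 5,
    "Participation": 8,
}


def paired_t(pre, post) -> StatResult:
    """Two-sided paired t-test on ``d = post - pre``."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ParameterError("pre and post must be paired (equal length)")
    n = pre.size
    if n < 2:
        raise ParameterError(f"paired t-test needs n >= 2, got {n}")
    d = post - pre
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return StatResult("paired_t", 0.0, n - 1, 1.0, 0.0, n)
        # all differences identical and nonzero: evidence is infinite
        return StatResult(
            "paired_t", float(np.sign(d.mean()) * np.inf), n - 1, 0.0, float(d.mean()), n
        )
    res = stats.ttest_rel(post, pre)
    return StatResult(
        kind="paired_t",
        statistic=float(res.statistic),
        df=n - 1,
        p_two_sided=float(res.pvalue),
        estimate=float(d.mean()),
        n=n,
    )


def t_to_p(t: float, df: int) -> float:
    """Exact two-sided tail probability of the central t distribution."""
    if df < 1:
        raise ParameterError(f"df must be >= 1, got {df}")
    return float(2.0 * stats.t.sf(abs(t), df))


def pearson(x, y) -> StatResult:
    """Pearson correlation; p from ``t = r sqrt(n-2) / sqrt(1-r^2)``, df = n-2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ParameterError("correlation inputs must have equal length")
    n = x.size
    if n < 3:
        raise ParameterError(f"correlation needs n >= 3, got {n}")
    if x.std() == 0 or y.std() == 0:
        raise DegenerateError("correlation undefined for a constant input")
    r, p = stats.pearsonr(x, y)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(max(1 - r * r, 0)) if abs(r) < 1 else np.inf * np.sign(r)
    return StatResult(
        kind="pearson",
        statistic=float(t),
        df=n - 2,
        p_two_sided=float(p),
        estimate=float(r),
        n=n,
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ParameterError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def sis_domains(subscale_raw_scores: dict, item_counts: dict = SIS_ITEM_COUNTS) -> SISDomainScores:
    """ICF domain scores from raw SIS subscale sums.

    Each subscale (items rated 1-5) is normalized with the instrument's
    standard transformation ``(mean item - 1) / 4 * 100``. Impairment is
    the normalized Strength subscale, Participation the normalized
    Participation subscale, and Function the unweighted mean of the
    normalized ADL and Hand Function subscales.
    """
    norm = {}
    for name in ("Strength", "ADL", "Hand Function", "Participation"):
        if name not in subscale_raw_scores:
            raise ParameterError(f"missing SIS subscale {name!r}")
        raw = float(subscale_raw_scores[name])
        count = int(item_counts[name])
        mean_item = raw / count
        if not 1.0 <= mean_item <= 5.0:
            raise ParameterError(
                f"{name}: mean item score {mean_item:.2f} outside the 1-5 SIS scale"
            )
        norm[name] = (mean_item - 1.0) / 4.0 * 100.0
    return SISDomainScores(
        impairment=norm["Strength"],
        function=(norm["ADL"] + norm["Hand Function"]) / 2.0,
        participation=norm["Participation"],
    )


def correlation_matrix(
    change_scores: pd.DataFrame,
    outcome_scores: pd.DataFrame,
    family: str = "matrix",
) -> pd.DataFrame:
    """All-pairs Pearson correlations with BH adjustment within the family.

    Rows = columns of ``change_scores``, columns = columns of
    ``outcome_scores``; every cell of the matrix belongs to the same BH
    family named ``family``.
    """
    cells = []
    for row in change_scores.columns:
        for col in outcome_scores.columns:
            paired = pd.concat(
                [change_scores[row], outcome_scores[col]], axis=1
            ).dropna()
            res = pearson(paired.iloc[:, 0], paired.iloc[:, 1])
            res.family = family
            cells.append((row, col, res))
    adjusted = bh_adjust([c[2].p_two_sided for c in cells])
    for (_, _, res), adj in zip(cells, adjusted):
        res.p_adjusted = float(adj)
    out = pd.DataFrame(
        index=change_scores.columns, columns=outcome_scores.columns, dtype=object
    )
    for row, col, res in cells:
        out.loc[row, col] = res
    return out


def _result_row(name: str, res: StatResult) -> dict:
    return {
        "measure": name,
        "t": res.statistic,
        "df": res.df,
        "p": res.p_two_sided,
        "mean_difference": res.estimate,
        "n": res.n,
    }


def group_report(
    clinical_table: ClinicalTable,
    er_results: dict | None = None,
    cmc_results: dict | None = None,
    sis_domain_columns: dict | None = None,
) -> dict:
    """Assemble the full pre/post group analysis.

    * paired t-tests for every measure in the table (pre vs post);
    * correlation matrices of ER-extension change and ROM-extension change
      against SIS domain scores, at both timepoints, each matrix one BH
      family;
    * if ``cmc_results`` provides per-participant pre/post laterality and
      peak coherence, a paired test on laterality per task and the
      peak-CMC-change vs FMA-change correlation.

    Missing measures are reported under ``"missing"`` rather than silently
    dropped. The report is a plain dict, JSON-serializable except for the
    embedded DataFrames (which the CLI flattens to CSV).
    """
    report: dict = {"n_participants": len(clinical_table.participants)}
    paired_rows = []
    missing = []
    for measure in clinical_table.measures:
        pre = clinical_table.pre(measure)
        post = clinical_table.post(measure)
        ok = np.isfinite(pre) & np.isfinite(post)
        if ok.sum() < 2:
            missing.append(measure)
            continue
        res = paired_t(pre[ok], post[ok])
        paired_rows.append(_result_row(measure, res))
    report["paired_tests"] = pd.DataFrame(paired_rows)
    report["missing"] = missing

    # correlation families: quantitative change vs perceived outcome domains
    domains = sis_domain_columns or {
        "Impairment": "SIS Strength",
        "Function": None,  # mean of ADL + Hand Function handled below
        "Participation": "SIS Participation",
    }
    measures = set(clinical_table.measures)
    sis_ok = {"SIS Strength", "SIS Participation", "SIS ADL", "SIS Hand Function"} <= measures
    if sis_ok:
        def domain_frame(timepoint: str) -> pd.DataFrame:
            get = clinical_table.pre if timepoint == "pre" else clinical_table.post
            return pd.DataFrame(
                {
                    "Impairment": get("SIS Strength"),
                    "Function": (get("SIS ADL") + get("SIS Hand Function")) / 2.0,
                    "Participation": get("SIS Participation"),
                },
                index=clinical_table.participants,
            )

        for quantity, label in (("ER extension", "er"), ("ROM extension", "rom")):
            if quantity not in measures:
                continue
            change = pd.DataFrame(
                {quantity + " change": clinical_table.change(quantity)},
                index=clinical_table.participants,
            )
            for timepoint in ("pre", "post"):
                key = f"correlations_{label}_{timepoint}"
                report[key] = correlation_matrix(
                    change, domain_frame(timepoint), family=f"{label}-{timepoint}"
                )

    if cmc_results:
        lat_rows = []
        for task, values in cmc_results.get("laterality", {}).items():
            pre_v = np.asarray(values["pre"], dtype=float)
            post_v = np.asarray(values["post"], dtype=float)
            res = paired_t(pre_v, post_v)
            lat_rows.append(_result_row(f"laterality ({task})", res))
        if lat_rows:
            report["laterality_tests"] = pd.DataFrame(lat_rows)
        peak = cmc_results.get("peak_cmc_change", {})
        if peak and "FMA" in measures:
            fma_change = clinical_table.change("FMA")
            rows = []
            for task, values in peak.items():
                res = pearson(np.asarray(values, dtype=float), fma_change)
                rows.append(
                    {
                        "task": task,
                        "r": res.estimate,
                        "df": res.df,
                        "p": res.p_two_sided,
                        "n": res.n,
                    }
                )
            report["peak_cmc_fma"] = pd.DataFrame(rows)

    if er_results:
        report["er_sessions"] = {
            key: {"mean_er": res.mean_er, "per_trial_er": list(res.per_trial_er)}
            for key, res in er_results.items()
        }
    return report
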