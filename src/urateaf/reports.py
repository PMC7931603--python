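"""Report-table and figure-data emitters.

Rendering conventions: percentages at one decimal with an explicit sign
for negative attributable fractions, odds ratios and betas at the
precisions the published tables use, and a ``^`` marker for
not-applicable cells.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

NA_MARK = "^"

__all__ = [
    "fmt_pct", "fmt_or", "fmt_beta",
    "render_table1", "render_table2", "render_table3", "render_table4",
    "fig1_long", "parse_table2",
]


def fmt_pct(x: float | None) -> str:
    """Proportion -> percent string at one decimal (e.g. 0.2114 -> '21.1')."""
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return NA_MARK
    return f"{100.0 * x:.1f}"


def fmt_or(x: float | None) -> str:
    if x is None or not np.isfinite(x):
        return NA_MARK
    return f"{x:.1f}"


def fmt_beta(x: float | None) -> str:
    if x is None or not np.isfinite(x):
        return NA_MARK
    return f"{x:.3f}"


def _pct_ci(lo, hi) -> str:
    return f"({fmt_pct(lo)}; {fmt_pct(hi)})"


def render_table1(design) -> pd.DataFrame:
    """Prevalence report: N (%) per exposure within each outcome group."""
    rows = []
    cases = design.outcome == 1
    for e in design.exposures.columns:
        col = design.exposures[e]
        n_case = int(col[cases].sum())
        n_ctrl = int(col[~cases].sum())
        rows.append({
            "exposure": e,
            "normouricaemia": f"{n_ctrl} ({100 * n_ctrl / max(design.n_controls, 1):.1f})",
            "hyperuricaemia": f"{n_case} ({100 * n_case / max(design.n_cases, 1):.1f})",
        })
    out = pd.DataFrame(rows).set_index("exposure")
    out.attrs["n_controls"] = design.n_controls
    out.attrs["n_cases"] = design.n_cases
    return out


def render_table2(af_table: pd.DataFrame, ci: dict | None = None) -> pd.DataFrame:
    """OR / PAF / AAF report from :meth:`AFResults.af_table` output plus
    optional bootstrap CI bundle from :func:`urateaf.af.bootstrap_intervals`."""
    rows = []
    for e, r in af_table.iterrows():
        row = {
            "exposure": e,
            "OR (95% CI)": f"{fmt_or(r['OR'])} ({fmt_or(r['OR_lo'])}; {fmt_or(r['OR_hi'])})",
            "PAF": fmt_pct(r["PAF"]),
            "AAF": fmt_pct(r["AAF"]),
        }
        if ci is not None:
            if "paf" in ci["ci"]:
                row["PAF 95% CI"] = _pct_ci(*ci["ci"]["paf"][e])
            if "aaf" in ci["ci"]:
                row["AAF 95% CI"] = _pct_ci(*ci["ci"]["aaf"][e])
        rows.append(row)
    return pd.DataFrame(rows).set_index("exposure")


def render_table3(variance_table: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for e, r in variance_table.iterrows():
        rows.append({
            "exposure": e,
            "Beta (95% CI)": f"{fmt_beta(r['beta'])} "
                             f"({fmt_beta(r['beta_lo'])}; {fmt_beta(r['beta_hi'])})",
            "R2 (%)": f"{r['partial_r2_pct']:.1f}",
        })
    return pd.DataFrame(rows).set_index("exposure")


def render_table4(mr_rows: dict[str, dict]) -> pd.DataFrame:
    """MR report: one row per exposure from `mr_analysis` result bundles."""
    rows = []
    for name, res in mr_rows.items():
        iv, eg, wm, call = (res["ivw"], res["egger"],
                            res["weighted_median"], res["call"])
        rows.append({
            "exposure": name,
            "n_snps": iv.n_snps,
            "IVW beta (95% CI)": f"{iv.theta:.3f} ({iv.ci95[0]:.3f}; {iv.ci95[1]:.3f})",
            "P_IVW": f"{iv.p:.2e}",
            "P_Het": f"{iv.p_het:.2e}" if iv.p_het is not None else NA_MARK,
            "Egger intercept": f"{eg.intercept:.2e}",
            "P_Intercept": f"{eg.intercept_p:.2f}",
            "WM beta (95% CI)": f"{wm.theta:.3f} ({wm.ci95[0]:.3f}; {wm.ci95[1]:.3f})",
            "P_WM": f"{wm.p:.2e}",
            "causal": call.causal,
        })
    return pd.DataFrame(rows).set_index("exposure")


def fig1_long(af_table: pd.DataFrame, variance_table: pd.DataFrame) -> pd.DataFrame:
    """Long-format (exposure, metric, value) data behind a PAF/AAF/R2 plot."""
    recs = []
    for e, r in af_table.iterrows():
        recs.append({"exposure": e, "metric": "PAF", "value": 100 * r["PAF"]})
        recs.append({"exposure": e, "metric": "AAF", "value": 100 * r["AAF"]})
    for e, r in variance_table.iterrows():
        recs.append({"exposure": e, "metric": "R2_pct",
                     "value": r["partial_r2_pct"]})
    return pd.DataFrame(recs)


def parse_table2(rendered: pd.DataFrame) -> pd.DataFrame:
    """Recover numeric OR/PAF/AAF values from a rendered AF report
    (round-trip at printed precision)."""
    out = []
    for e, r in rendered.iterrows():
        or_part = r["OR (95% CI)"].split(" (")
        out.append({
            "exposure": e,
            "OR": float(or_part[0]),
            "PAF": float(r["PAF"]) / 100.0 if r["PAF"] != NA_MARK else np.nan,
            "AAF": float(r["AAF"]) / 100.0 if r["AAF"] != NA_MARK else np.nan,
        })
    return pd.DataFrame(out).set_index("exposure")
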