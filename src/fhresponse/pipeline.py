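"""End-to-end analysis: responses, genotype groups, scores, study tables.

The pipeline consumes three CSV-shaped tables —

* cohort: ``patient_id, pre_ldl, post_ldl, statin_agent, statin_dose_mg,
  ezetimibe, evolocumab, pre_evolocumab_ldl, post_evolocumab_ldl,
  followup_months``
* variants: ``patient_id, gene, cdna_hgvs, protein_hgvs, variant_class,
  zygosity``
* genotypes: ``patient_id`` plus one dosage column per rsID

— and produces a report bundle: the per-patient response table, the
group-comparison table (baseline/post LDL-C, percent reduction, achieved %
of expected, and target attainment across PV groups, with Mann-Whitney and
contingency p-values), the score-response regressions, and an evolocumab
add-on report when those columns are populated.

Patients whose regimen cannot be mapped to an expected reduction, or who
lack an LDL-C measurement, are excluded row-by-row with a reason; the run
continues and the exclusion accounting (n analysed + n excluded = n input)
is part of the bundle.  Internal computation is full precision; rounding
happens only in the formatted report columns.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import stats
from .errors import FHResponseError, UnmappedAgentError, UnmappedRegimenError
from .regimen import ExpectedReductionTable, Regimen, StatinDose
from .response import (
    LipidPanel,
    achieved_pct_of_expected,
    percent_reduction,
    round_half_away,
    target_attainment,
)
from .snpscore import SNPWeight, placeholder_weights, score_table
from .variants import (
    DEFAULT_REPEAT5_RANGE,
    PVGroup,
    VariantRecord,
    classify_patient,
    classify_variant,
)

logger = logging.getLogger(__name__)

COHORT_COLUMNS = [
    "patient_id",
    "pre_ldl",
    "post_ldl",
    "statin_agent",
    "statin_dose_mg",
    "ezetimibe",
]
VARIANT_COLUMNS = ["patient_id", "gene", "cdna_hgvs"]


@dataclass
class ReportBundle:
    responses: pd.DataFrame
    exclusions: pd.DataFrame
    comparison: pd.DataFrame
    regressions: pd.DataFrame
    evolocumab: pd.DataFrame | None
    summary_markdown: str

    def write(self, outdir) -> None:
        os.makedirs(outdir, exist_ok=True)
        self.responses.to_csv(os.path.join(outdir, "responses.csv"), index=False)
        self.exclusions.to_csv(os.path.join(outdir, "exclusions.csv"), index=False)
        self.comparison.to_csv(os.path.join(outdir, "group_comparison.csv"), index=False)
        self.regressions.to_csv(os.path.join(outdir, "regressions.csv"), index=False)
        if self.evolocumab is not None:
            self.evolocumab.to_csv(os.path.join(outdir, "evolocumab.csv"), index=False)
        with open(os.path.join(outdir, "summary.md"), "w") as fh:
            fh.write(self.summary_markdown)


def _to_bool(x) -> bool:
    if isinstance(x, str):
        return x.strip().lower() in ("1", "true", "yes", "y")
    return bool(x) and not pd.isna(x)


def compute_responses(
    cohort: pd.DataFrame, table: ExpectedReductionTable | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-patient observed reduction and achieved % of expected.

    Returns ``(responses, exclusions)``; exclusions carry a per-row reason
    (``missing_ldl`` or ``unmapped_regimen``) and the offending detail.
    """
    table = table or ExpectedReductionTable()
    cache: dict[tuple, float] = {}
    rows, excluded = [], []
    for rec in cohort.to_dict("records"):
        pid = rec["patient_id"]
        pre, post = rec.get("pre_ldl"), rec.get("post_ldl")
        if pd.isna(pre) or pd.isna(post):
            excluded.append({"patient_id": pid, "reason": "missing_ldl", "detail": ""})
            continue
        if not float(pre) > 0:
            excluded.append(
                {"patient_id": pid, "reason": "missing_ldl", "detail": f"pre_ldl={pre}"}
            )
            continue
        key = (
            str(rec.get("statin_agent", "")).strip().lower(),
            float(rec["statin_dose_mg"]) if pd.notna(rec.get("statin_dose_mg")) else None,
            _to_bool(rec.get("ezetimibe", False)),
        )
        try:
            if key not in cache:
                statin = StatinDose(key[0], key[1]) if key[0] and key[1] else None
                cache[key] = table.expected_reduction(Regimen(statin=statin, ezetimibe=key[2]))
            expected = cache[key]
        except (UnmappedAgentError, UnmappedRegimenError, ValueError) as exc:
            excluded.append(
                {"patient_id": pid, "reason": "unmapped_regimen", "detail": str(exc)}
            )
            continue
        panel = LipidPanel(float(pre), float(post))
        delta = percent_reduction(panel)
        row = {
            "patient_id": pid,
            "pre_ldl": float(pre),
            "post_ldl": float(post),
            "expected_pct": expected,
            "delta_pct": delta,
            "achieved_pct": achieved_pct_of_expected(delta, expected),
            "target_met": target_attainment(float(post)),
        }
        if _to_bool(rec.get("evolocumab", False)) and pd.notna(
            rec.get("pre_evolocumab_ldl")
        ) and pd.notna(rec.get("post_evolocumab_ldl")):
            epanel = LipidPanel(float(rec["pre_evolocumab_ldl"]), float(rec["post_evolocumab_ldl"]))
            addon = table.expected_reduction_addon(True)
            edelta = percent_reduction(epanel)
            row.update(
                evo_pre_ldl=epanel.pre_ldl,
                evo_post_ldl=epanel.post_ldl,
                evo_delta_pct=edelta,
                evo_achieved_pct=achieved_pct_of_expected(edelta, addon),
                evo_target_met=target_attainment(epanel.post_ldl),
            )
        rows.append(row)
    responses = pd.DataFrame(rows)
    exclusions = pd.DataFrame(excluded, columns=["patient_id", "reason", "detail"])
    return responses, exclusions


def classify_cohort(
    variants: pd.DataFrame,
    patient_ids: Sequence[str],
    repeat5_range: tuple[int, int] = DEFAULT_REPEAT5_RANGE,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Patient-level PV groups and a variant-level classification report.

    Patients absent from the variant table are PV-negative.  Returns
    ``(groups, variant_report)``.
    """
    records: dict[str, list[VariantRecord]] = {str(p): [] for p in patient_ids}
    vrows = []
    for rec in variants.to_dict("records"):
        v = VariantRecord(
            gene=rec["gene"],
            cdna_hgvs=rec["cdna_hgvs"],
            protein_hgvs=(rec.get("protein_hgvs") or None)
            if pd.notna(rec.get("protein_hgvs"))
            else None,
            variant_class=(rec.get("variant_class") or None)
            if pd.notna(rec.get("variant_class"))
            else None,
            zygosity=rec.get("zygosity") or "heterozygous",
        )
        pid = str(rec["patient_id"])
        records.setdefault(pid, []).append(v)
        vrows.append({**rec, "pv_class": classify_variant(v, repeat5_range).value})
    grows = []
    for pid, vs in records.items():
        g = classify_patient(vs, repeat5_range)
        grows.append(
            {"patient_id": pid, "pv_group": g.group.value, "has_any_null": g.has_any_null}
        )
    groups = pd.DataFrame(grows)
    variant_report = pd.DataFrame(vrows) if vrows else pd.DataFrame(
        columns=list(variants.columns) + ["pv_class"]
    )
    return groups, variant_report


def _fmt_summary(values, ndigits: int) -> str:
    s = stats.group_summary(values)
    fmt = lambda v: f"{round_half_away(v, ndigits):.{max(ndigits, 0)}f}" if ndigits else f"{round_half_away(v, 0):.0f}"
    return f"{fmt(s.median)} ({fmt(s.q1)}, {fmt(s.q3)})"


def _safe_mwu_p(a, b) -> float:
    if len(a) == 0 or len(b) == 0:
        return float("nan")
    return stats.mann_whitney(a, b).p_two_sided


_GROUP_COLUMNS = (
    ("total", lambda df: np.ones(len(df), dtype=bool)),
    ("pv_negative", lambda df: df["pv_group"] == PVGroup.PV_NEGATIVE.value),
    ("pv_positive", lambda df: df["pv_group"] != PVGroup.PV_NEGATIVE.value),
    (
        "ldlr_any",
        lambda df: df["pv_group"].isin(
            [PVGroup.LDLR_NULL.value, PVGroup.LDLR_DEFECTIVE.value, PVGroup.COMPOUND_OR_HOMOZYGOUS.value]
        ),
    ),
    ("ldlr_null", lambda df: df["pv_group"] == PVGroup.LDLR_NULL.value),
    ("ldlr_defective", lambda df: df["pv_group"] == PVGroup.LDLR_DEFECTIVE.value),
    ("apob_pcsk9", lambda df: df["pv_group"] == PVGroup.APOB_PCSK9.value),
)

_METRICS = (
    ("pre_ldl", "Pre-treatment LDL-C, mg/dL", 0),
    ("post_ldl", "Post-treatment LDL-C, mg/dL", 0),
    ("delta_pct", "LDL-C reduction, %", 1),
    ("achieved_pct", "LDL-C reduction, % of expected value", 1),
)


def group_comparison(merged: pd.DataFrame) -> pd.DataFrame:
    """The study-style group table: summaries per PV group plus p-values.

    p columns: PV-positive vs PV-negative; LDLR carriers vs APOB/PCSK9
    carriers; null vs defective LDLR.  Target attainment is compared with
    the chi-square/Fisher contingency test, the continuous metrics with
    Mann-Whitney.
    """
    masks = {name: fn(merged) for name, fn in _GROUP_COLUMNS}
    rows = []
    for col, label, nd in _METRICS:
        vals = {name: merged.loc[m, col].to_numpy() for name, m in masks.items()}
        row = {"metric": label}
        for name, v in vals.items():
            row[name] = _fmt_summary(v, nd) if len(v) else ""
        row["p_pos_vs_neg"] = _safe_mwu_p(vals["pv_positive"], vals["pv_negative"])
        row["p_ldlr_vs_apob_pcsk9"] = _safe_mwu_p(vals["ldlr_any"], vals["apob_pcsk9"])
        row["p_null_vs_defective"] = _safe_mwu_p(vals["ldlr_null"], vals["ldlr_defective"])
        rows.append(row)

    # target attainment: n (%) per group, contingency p for pos vs neg
    row = {"metric": "Achievement of LDL-C < 70 mg/dL, n (%)"}
    for name, m in masks.items():
        sub = merged.loc[m, "target_met"]
        row[name] = f"{int(sub.sum())} ({100 * sub.mean():.1f})" if len(sub) else ""
    tab = [
        [int(merged.loc[masks["pv_positive"], "target_met"].sum()),
         int((~merged.loc[masks["pv_positive"], "target_met"]).sum())],
        [int(merged.loc[masks["pv_negative"], "target_met"].sum()),
         int((~merged.loc[masks["pv_negative"], "target_met"]).sum())],
    ]
    try:
        row["p_pos_vs_neg"] = stats.contingency_test(tab).p_value
    except FHResponseError:
        row["p_pos_vs_neg"] = float("nan")
    row["p_ldlr_vs_apob_pcsk9"] = float("nan")
    row["p_null_vs_defective"] = float("nan")
    rows.append(row)
    return pd.DataFrame(rows)


def score_regressions(merged: pd.DataFrame) -> pd.DataFrame:
    """OLS of achieved % of expected on the weighted SNP score.

    Fitted on the full analysed cohort, on patients without any null PV,
    and on PV-negative patients only; subsets too small or degenerate are
    skipped.
    """
    subsets = {
        "all": np.ones(len(merged), dtype=bool),
        "without_null_pv": ~merged["has_any_null"].fillna(False).astype(bool).to_numpy(),
        "pv_negative": (merged["pv_group"] == PVGroup.PV_NEGATIVE.value).to_numpy(),
    }
    rows = []
    for name, mask in subsets.items():
        sub = merged.loc[mask & merged["score"].notna() & merged["achieved_pct"].notna()]
        if len(sub) < 3 or sub["score"].nunique() < 2:
            continue
        fit = stats.linear_regression(sub["score"], sub["achieved_pct"])
        rows.append(
            {
                "subset": name,
                "n": fit.n,
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r_squared": fit.r_squared,
                "p_slope": fit.p_slope,
            }
        )
    return pd.DataFrame(rows, columns=["subset", "n", "slope", "intercept", "r_squared", "p_slope"])


def evolocumab_report(merged: pd.DataFrame) -> pd.DataFrame | None:
    """Per-patient evolocumab add-on table plus a PV-positive summary row."""
    if "evo_achieved_pct" not in merged.columns:
        return None
    sub = merged[merged["evo_achieved_pct"].notna()].copy()
    if sub.empty:
        return None
    out = sub[
        ["patient_id", "pv_group", "evo_pre_ldl", "evo_post_ldl", "evo_delta_pct", "evo_achieved_pct"]
    ].copy()
    out["evo_delta_pct"] = out["evo_delta_pct"].map(lambda v: round_half_away(v, 1))
    out["evo_achieved_pct"] = out["evo_achieved_pct"].map(lambda v: round_half_away(v, 1))
    pos = sub[sub["pv_group"] != PVGroup.PV_NEGATIVE.value]
    if len(pos):
        summary = {
            "patient_id": "PV_POSITIVE_SUMMARY",
            "pv_group": f"n={len(pos)}",
            "evo_pre_ldl": _fmt_summary(pos["evo_pre_ldl"], 0),
            "evo_post_ldl": _fmt_summary(pos["evo_post_ldl"], 0),
            "evo_delta_pct": _fmt_summary(pos["evo_delta_pct"], 1),
            "evo_achieved_pct": _fmt_summary(pos["evo_achieved_pct"], 1),
        }
        out = pd.concat([out, pd.DataFrame([summary])], ignore_index=True)
    return out


def run_analysis(
    cohort: pd.DataFrame,
    variants: pd.DataFrame,
    genotypes: pd.DataFrame | None = None,
    weights: Sequence[SNPWeight] | None = None,
    table: ExpectedReductionTable | None = None,
    repeat5_range: tuple[int, int] = DEFAULT_REPEAT5_RANGE,
) -> ReportBundle:
    """Run the full analysis and assemble the report bundle."""
    table = table or ExpectedReductionTable()
    responses, exclusions = compute_responses(cohort, table)
    if responses.empty:
        raise FHResponseError("no analysable patients after exclusions")
    groups, _variant_report = classify_cohort(
        variants, cohort["patient_id"].astype(str), repeat5_range
    )
    merged = responses.copy()
    merged["patient_id"] = merged["patient_id"].astype(str)
    merged = merged.merge(groups, on="patient_id", how="left")
    merged["pv_group"] = merged["pv_group"].fillna(PVGroup.PV_NEGATIVE.value)
    merged["has_any_null"] = merged["has_any_null"].fillna(False)

    if genotypes is not None:
        weights = list(weights) if weights is not None else placeholder_weights()
        scores = score_table(genotypes, weights)
        scores["patient_id"] = scores["patient_id"].astype(str)
        merged = merged.merge(scores[["patient_id", "score"]], on="patient_id", how="left")
    else:
        merged["score"] = np.nan

    comparison = group_comparison(merged)
    regressions = score_regressions(merged)
    evolocumab = evolocumab_report(merged)

    n_in = len(cohort)
    n_used = len(merged)
    by_reason = exclusions["reason"].value_counts().to_dict() if len(exclusions) else {}
    logger.info(
        "analysed %d of %d patients (excluded: %s)", n_used, n_in, by_reason or "none"
    )
    lines = [
        "# Treatment-response analysis summary",
        "",
        f"- patients in input: {n_in}",
        f"- patients analysed: {n_used}",
        f"- patients excluded: {len(exclusions)}"
        + (f" ({', '.join(f'{k}: {v}' for k, v in by_reason.items())})" if by_reason else ""),
        "",
        "## Group comparison",
        "",
        "```",
        comparison.to_string(index=False),
        "```",
        "",
        "## SNP-score regressions",
        "",
        "```",
        regressions.to_string(index=False) if len(regressions) else "(not computed)",
        "```",
    ]
    if evolocumab is not None:
        lines += ["", "## Evolocumab add-on", "", "```", evolocumab.to_string(index=False), "```"]
    return ReportBundle(
        responses=merged,
        exclusions=exclusions,
        comparison=comparison,
        regressions=regressions,
        evolocumab=evolocumab,
        summary_markdown="\n".join(lines) + "\n",
    )


def validate_inputs(
    cohort: pd.DataFrame,
    variants: pd.DataFrame | None = None,
    genotypes: pd.DataFrame | None = None,
    rsids: Sequence[str] | None = None,
) -> list[str]:
    """Schema and referential-integrity checks; returns row-addressed issues."""
    issues: list[str] = []
    for col in COHORT_COLUMNS:
        if col not in cohort.columns:
            issues.append(f"cohort: missing column {col!r}")
    if "patient_id" not in cohort.columns:
        return issues
    ids = set(cohort["patient_id"].astype(str))
    if len(ids) != len(cohort):
        issues.append("cohort: duplicate patient_id values")
    if "pre_ldl" in cohort.columns:
        bad = cohort[cohort["pre_ldl"].notna() & ~(cohort["pre_ldl"] > 0)]
        issues += [
            f"cohort: pre_ldl must be > 0 (patient_id={r.patient_id}, pre_ldl={r.pre_ldl})"
            for r in bad.itertuples()
        ]
    if variants is not None:
        for col in VARIANT_COLUMNS:
            if col not in variants.columns:
                issues.append(f"variants: missing column {col!r}")
        if "patient_id" in variants.columns:
            orphans = set(variants["patient_id"].astype(str)) - ids
            issues += [f"variants: unknown patient_id {p}" for p in sorted(orphans)]
    if genotypes is not None:
        if "patient_id" in genotypes.columns:
            orphans = set(genotypes["patient_id"].astype(str)) - ids
            issues += [f"genotypes: unknown patient_id {p}" for p in sorted(orphans)]
        for col in rsids or [c for c in genotypes.columns if c.startswith("rs")]:
            if col not in genotypes.columns:
                issues.append(f"genotypes: missing dosage column {col!r}")
                continue
            vals = genotypes[col]
            bad = genotypes[vals.notna() & ~vals.isin([0, 1, 2])]
            issues += [
                f"genotypes: dosage out of bounds (patient_id={r.patient_id}, {col}={getattr(r, col)})"
                for r in bad.itertuples()
            ]
    return issues
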