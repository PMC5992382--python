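"""qPCR-scaled R-OTU decontamination against background controls.

The idea: multiplying each OTU's relative abundance by the sample's 16S
qPCR copy number gives an "absolute" abundance comparable across samples of
very different biomass. The R-OTU score of an OTU is the ratio of its mean
absolute abundance in background controls to that in specimens; scores above
a small cutoff (default 0.01) mark contaminants, which are removed globally
(from controls as well as specimens — proportional removal). Because an
endogenous taxon carried over into controls scales with the specimen pool,
its score stays near the carryover rate, far below the cutoff, whereas a
reagent/air contaminant present at comparable copy numbers in controls and
specimens scores near 1.

Conventions: means are arithmetic over the samples of a role, zeros
included; an OTU absent from every control scores 0 (never flagged); one
present in controls but absent from every specimen scores +inf (always
flagged); removal is strict (> threshold), so a score exactly at the cutoff
is retained.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .model import (
    ConfigurationError,
    OtuTable,
    Profile,
    ROtuReport,
    SampleSheet,
    ValidationError,
)

__all__ = ["absolute_abundance", "r_otu_scores", "decontaminate",
           "remove_contaminants", "retention_report"]

log = logging.getLogger("cryoclean")


def absolute_abundance(profile: Profile, sheet: SampleSheet) -> pd.DataFrame:
    """Relative abundance x qPCR copies/μl, per sample x OTU."""
    missing = [s for s in profile.sample_ids if s not in sheet.df.index]
    if missing:
        raise ValidationError(f"no qPCR value for sample(s) {missing}")
    qpcr = sheet.qpcr().reindex(profile.sample_ids)
    return profile.rel_abund.mul(qpcr, axis=0)


def r_otu_scores(abs_abund: pd.DataFrame, sheet: SampleSheet,
                 threshold: float = 0.01) -> ROtuReport:
    """Score every OTU by its control/specimen absolute-abundance ratio."""
    sheet.require_cover(abs_abund.index)
    sheet.require_roles()
    controls = [s for s in sheet.controls() if s in abs_abund.index]
    specimens = [s for s in sheet.specimens() if s in abs_abund.index]
    if not controls or not specimens:
        raise ConfigurationError(
            "the abundance matrix must include at least one control and one "
            "specimen sample"
        )
    cols = abs_abund.columns
    c = abs_abund.loc[controls].to_numpy(float).mean(axis=0)
    s = abs_abund.loc[specimens].to_numpy(float).mean(axis=0)
    mean_c = pd.Series(c, index=cols)
    mean_s = pd.Series(s, index=cols)
    r = np.zeros_like(c)
    both = (c > 0) & (s > 0)
    r[both] = c[both] / s[both]
    r[(c > 0) & (s == 0)] = np.inf  # seen only in controls: unambiguous contaminant
    scores = pd.DataFrame({
        "mean_abs_control": mean_c,
        "mean_abs_specimen": mean_s,
        "r_otu": r,
    })
    scores["is_contaminant"] = scores["r_otu"] > threshold
    return ROtuReport(scores=scores, threshold=threshold)


def decontaminate(table: OtuTable, report: ROtuReport,
                  threshold: float | None = None) -> tuple[OtuTable, ROtuReport]:
    """Remove flagged OTUs from every sample and account for retention.

    OTUs with ``r_otu`` strictly above the threshold are dropped globally.
    ``reads_retained_fraction`` per sample is retained/original counts; an
    originally empty sample reports 1.0 with an explicit ``empty`` flag so
    downstream summaries stay numeric.
    """
    if threshold is not None:
        if threshold <= 0:
            raise ConfigurationError(f"threshold must be positive, got {threshold}")
        report = ROtuReport(scores=report.scores.copy(), threshold=threshold)
        report.scores["is_contaminant"] = report.scores["r_otu"] > threshold
    missing = [o for o in table.otu_ids if o not in report.scores.index]
    if missing:
        raise ValidationError(f"R-OTU report has no score for OTU(s) {missing}")
    flagged = [o for o in table.otu_ids
               if bool(report.scores.loc[o, "is_contaminant"])]
    clean = table.drop_otus(flagged)
    before = table.sample_totals().astype(float)
    after = clean.sample_totals().astype(float)
    empty = before == 0
    fraction = (after / before.where(~empty, 1.0)).where(~empty, 1.0)
    retention = pd.DataFrame({
        "reads_retained_fraction": fraction,
        "empty": empty,
    })
    retention.index.name = "sample_id"
    log.info("decontaminate: removed %d/%d OTUs at threshold %g",
             len(flagged), len(table.otu_ids), report.threshold)
    return clean, ROtuReport(scores=report.scores, threshold=report.threshold,
                             retention=retention)


def remove_contaminants(table: OtuTable, sheet: SampleSheet,
                        threshold: float = 0.01,
                        ) -> tuple[OtuTable, ROtuReport]:
    """End-to-end proportional removal on one table.

    Computes OTU-level relative abundances, scales them by the sheet's qPCR
    copy numbers, scores R-OTU, and removes OTUs scoring strictly above
    ``threshold``.
    """
    if threshold <= 0:
        raise ConfigurationError(f"threshold must be positive, got {threshold}")
    profile = table.relative_abundance()
    abs_ab = absolute_abundance(profile, sheet)
    report = r_otu_scores(abs_ab, sheet, threshold=threshold)
    return decontaminate(table, report)


def retention_report(report: ROtuReport, sheet: SampleSheet) -> pd.DataFrame:
    """Per-sample retained fractions plus min/max per role.

    Rows for samples carry their role; two summary rows per role carry the
    minimum and maximum retained fraction (the paper-style "93.2–97.8%
    retained in specimens" range).
    """
    if report.retention is None:
        raise ConfigurationError("run decontaminate before retention_report")
    rows = []
    ret = report.retention
    for sid in ret.index:
        role = sheet.df.loc[sid, "role"] if sid in sheet.df.index else ""
        rows.append({"sample_id": sid, "role": role,
                     "reads_retained_fraction": float(
                         ret.loc[sid, "reads_retained_fraction"]),
                     "empty": bool(ret.loc[sid, "empty"])})
    out = pd.DataFrame(rows)
    for role in sorted(set(out["role"]) - {""}):
        vals = out.loc[out["role"] == role, "reads_retained_fraction"]
        for stat, val in (("min", vals.min()), ("max", vals.max())):
            rows.append({"sample_id": f"{role}_{stat}", "role": role,
                         "reads_retained_fraction": float(val), "empty": False})
    return pd.DataFrame(rows)
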