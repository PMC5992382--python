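"""End-to-end orchestration of the decontamination workflow.

Stage order is fixed: load & validate -> organelle removal -> rarefaction ->
R-OTU decontamination -> genus profiles & major taxa -> community statistics.
Organelle removal precedes rarefaction (so organellar reads never consume
rarefaction depth) and decontamination follows it (R-OTU ratios are computed
on the depth-normalised table); both choices are echoed into the run
manifest. All randomness flows from one master seed expanded per stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .decontam import remove_contaminants, retention_report
from .model import ConfigurationError, CryocleanError
from .profiling import collapse_taxonomy, heatmap_matrix, rarefy, \
    remove_organelles, select_major_taxa
from .stats import anosim, pcoa, upgma, weighted_unifrac

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("cryoclean")


@dataclass
class RunConfig:
    """Fully serialisable configuration of one pipeline run."""

    otu_table: str
    sample_sheet: str
    taxonomy: str
    out_dir: str
    tree: str | None = None
    otu_table_dialect: str = "tsv_samples_as_rows"
    confidence_threshold: float = 0.80
    rarefaction_depth: int = 30000
    decontam_threshold: float = 0.01
    collapse_rank: str = "genus"
    major_taxa_threshold: float = 0.01
    major_taxa_comparator: str = ">="
    unifrac_variant: str = "raw"
    permutations: int = 999
    master_seed: int = 1

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigurationError(f"incomplete config {path}: {exc}") from exc

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def stage_seeds(self) -> dict[str, int]:
        state = np.random.SeedSequence(self.master_seed).generate_state(2)
        return {"rarefy": int(state[0]) % (2 ** 31),
                "stats": int(state[1]) % (2 ** 31)}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage, writing artifacts and a manifest; returns the manifest.

    Any stage failure raises a :class:`CryocleanError` naming the stage;
    reruns with an identical config are bit-identical.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()
    manifest: dict = {"config": config.to_dict(), "stage_seeds": seeds,
                      "stages": [], "outputs": {}}

    def record(stage: str, **info):
        manifest["stages"].append({"stage": stage, **info})
        log.info("stage %s: %s", stage, info)

    def emit(name: str, path: Path):
        manifest["outputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    stage = "load"
    try:
        table = cio.read_otu_table(config.otu_table, config.otu_table_dialect)
        sheet = cio.read_sample_sheet(config.sample_sheet)
        tax = cio.read_taxonomy(config.taxonomy, config.confidence_threshold)
        sheet.require_cover(table.sample_ids)
        tax.require_cover(table.otu_ids)
        tree = cio.read_newick(config.tree) if config.tree else None
        record(stage, samples=len(table.sample_ids), otus=len(table.otu_ids))

        stage = "organelle_filter"
        table = remove_organelles(table, tax)
        record(stage, otus=len(table.otu_ids))

        stage = "rarefy"
        table = rarefy(table, config.rarefaction_depth, seeds["rarefy"])
        path = out / "rarefied_table.tsv"
        cio.write_otu_table(table, path)
        emit("rarefied_table", path)
        record(stage, depth=config.rarefaction_depth,
               samples=len(table.sample_ids), seed=seeds["rarefy"])

        stage = "decontaminate"
        clean, report = remove_contaminants(table, sheet,
                                            config.decontam_threshold)
        path = out / "clean_table.tsv"
        cio.write_otu_table(clean, path)
        emit("clean_table", path)
        scores = report.scores.copy()
        scores.index.name = "otu_id"
        scores.to_csv(out / "rotu_report.tsv", sep="\t")
        emit("rotu_report", out / "rotu_report.tsv")
        retention_report(report, sheet).to_csv(out / "retention.tsv",
                                               sep="\t", index=False)
        emit("retention", out / "retention.tsv")
        record(stage, threshold=config.decontam_threshold,
               contaminants=len(report.contaminants()))

        stage = "profiles"
        profile = collapse_taxonomy(clean, tax, config.collapse_rank)
        profile.rel_abund.to_csv(out / "genus_profile.tsv", sep="\t")
        emit("genus_profile", out / "genus_profile.tsv")
        major = select_major_taxa(profile, config.major_taxa_threshold,
                                  comparator=config.major_taxa_comparator)
        (out / "major_taxa.tsv").write_text(
            "taxon\n" + "".join(f"{t}\n" for t in major))
        emit("major_taxa", out / "major_taxa.tsv")
        hm = heatmap_matrix(table, config.rarefaction_depth)
        hm.index.name = "sample_id"
        hm.to_csv(out / "heatmap_matrix.tsv", sep="\t")
        emit("heatmap_matrix", out / "heatmap_matrix.tsv")
        record(stage, major_taxa=len(major))

        stage = "stats"
        stats_done = {}
        if tree is not None:
            dm = weighted_unifrac(clean, tree, config.unifrac_variant)
            cio.write_distance_matrix(dm, out / "weighted_unifrac.tsv")
            emit("weighted_unifrac", out / "weighted_unifrac.tsv")
            ord_ = pcoa(dm)
            coords = np.asarray(ord_.coordinates)
            cdf = pd.DataFrame(
                coords, index=ord_.sample_ids,
                columns=[f"PCo{k + 1}" for k in range(coords.shape[1])])
            cdf.index.name = "sample_id"
            cdf.to_csv(out / "pcoa_coordinates.tsv", sep="\t")
            emit("pcoa_coordinates", out / "pcoa_coordinates.tsv")
            (out / "pcoa_proportion_explained.tsv").write_text(
                "axis\tproportion\n" + "".join(
                    f"PCo{k + 1}\t{p:.10g}\n"
                    for k, p in enumerate(ord_.proportion_explained)))
            emit("pcoa_proportion_explained",
                 out / "pcoa_proportion_explained.tsv")
            dendro = upgma(dm)
            (out / "upgma.nwk").write_text(dendro.to_newick() + "\n")
            emit("upgma", out / "upgma.nwk")
            stats_done["unifrac"] = True
            specimens = [s for s in clean.sample_ids
                         if s in set(sheet.specimens())]
            spec_groups = sheet.groups().reindex(specimens)
            if len(specimens) >= 3 and spec_groups.nunique() >= 2:
                result = anosim(dm.filter(specimens), list(spec_groups),
                                permutations=config.permutations,
                                seed=seeds["stats"])
                (out / "anosim.tsv").write_text(
                    "statistic\tp_value\tpermutations\tseed\n"
                    f"{result.statistic:.10g}\t{result.p_value:.10g}\t"
                    f"{result.permutations}\t{seeds['stats']}\n")
                emit("anosim", out / "anosim.tsv")
                stats_done["anosim"] = {"R": result.statistic,
                                        "p": result.p_value}
        record(stage, **({"ran": sorted(stats_done)} if stats_done
                         else {"ran": []}))
    except CryocleanError as exc:
        raise CryocleanError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True,
                                        default=str) + "\n")
    return manifest
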