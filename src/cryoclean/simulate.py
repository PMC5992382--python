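"""Mock low-biomass amplicon experiments with known ground truth.

The generator reproduces the statistical structure the decontamination
method assumes: a handful of specimen libraries with ~10^3 16S copies/μl, a
shared ambient contaminant pool that dominates the much lower-biomass
background controls (~40 copies/μl, a 50x contrast), directed carryover of
specimen templates into controls (cross-contamination from high- to
low-biomass samples), lognormal qPCR measurement noise, multinomial
sequencing at a fixed depth, and optional two-round PCR amplification bias
(28 + 8 cycles with per-template efficiencies).

Specimens also carry the ambient contaminant pool at control-level copy
numbers — the scenario in which proportional (ratio-based) removal, rather
than naive presence/absence exclusion, is the behaviour worth testing.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import skbio

from .model import ConfigurationError, OtuTable, SampleSheet, TaxonomyTable
from .qc import QualRead, write_fastq

__all__ = ["SimConfig", "SimTruth", "simulate_experiment", "apply_pcr_bias",
           "emit_fastq", "tag_for_otu", "tally_reads", "simulate_tree"]


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for one mock experiment.

    Defaults mirror a four-specimen / four-control design with a 50x biomass
    contrast (2,000 vs 40 copies/μl), sequencing depth 30,000 and 28+8 PCR
    cycles. ``carryover_fraction`` is the fraction of the mean specimen
    template pool that leaks into each control during co-processing; its
    default 5e-4 reproduces the few-percent specimen-derived read fraction
    observed in real background controls (see docs/methods.md).
    """

    n_specimens: int = 4
    n_controls: int = 4
    n_endogenous_otus: int = 20
    n_contaminant_otus: int = 20
    specimen_copies_per_ul: float = 2000.0
    control_copies_per_ul: float = 40.0
    dirichlet_concentration: float = 1.0
    carryover_fraction: float = 5e-4
    read_depth: int = 30000
    qpcr_cv: float = 0.10
    pcr_cycles: tuple[int, int] = (28, 8)
    pcr_efficiency_range: tuple[float, float] = (0.9, 1.0)
    apply_pcr: bool = False
    n_groups: int = 2
    seed: int = 0

    def __post_init__(self):
        if min(self.n_specimens, self.n_controls, self.n_endogenous_otus,
               self.n_contaminant_otus, self.read_depth, self.n_groups) <= 0:
            raise ConfigurationError("all design counts must be positive")
        if not 0.0 <= self.carryover_fraction < 1.0:
            raise ConfigurationError("carryover_fraction must lie in [0, 1)")
        if min(self.specimen_copies_per_ul, self.control_copies_per_ul,
               self.dirichlet_concentration) <= 0:
            raise ConfigurationError("copy numbers and concentration must be positive")
        lo, hi = self.pcr_efficiency_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ConfigurationError("pcr_efficiency_range must lie within (0, 1]")
        if self.qpcr_cv < 0:
            raise ConfigurationError("qpcr_cv must be non-negative")
        if self.n_groups > self.n_specimens:
            raise ConfigurationError("more groups than specimens")


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated experiment."""

    origin: pd.Series  # per OTU: "endogenous" | "contaminant"
    true_pools: pd.DataFrame  # samples x OTUs, copies/μl
    true_totals: pd.Series  # per sample, copies/μl
    group_communities: pd.DataFrame  # groups x endogenous OTUs, proportions
    contaminant_community: pd.Series  # proportions over contaminant OTUs

    def contaminant_otus(self) -> list[str]:
        return list(self.origin.index[self.origin == "contaminant"])

    def endogenous_otus(self) -> list[str]:
        return list(self.origin.index[self.origin == "endogenous"])


def _lognormal_factors(rng: np.ndarray, cv: float, size: int) -> np.ndarray:
    """Mean-1 lognormal multipliers with coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv ** 2))
    return rng.lognormal(mean=-sigma ** 2 / 2.0, sigma=sigma, size=size)


def apply_pcr_bias(pool: np.ndarray, cycles: tuple[int, int],
                   efficiencies: np.ndarray) -> np.ndarray:
    """Two-round amplification distortion of a template composition.

    Template i is weighted by (1 + e_i)^(c1 + c2) and the composition
    renormalised; equal efficiencies leave it unchanged, and zero cycles are
    the identity.
    """
    pool = np.asarray(pool, dtype=float)
    eff = np.asarray(efficiencies, dtype=float)
    if np.any((eff <= 0) | (eff > 1)):
        raise ConfigurationError("PCR efficiencies must lie in (0, 1]")
    total_cycles = int(cycles[0]) + int(cycles[1])
    weights = pool * np.power(1.0 + eff, total_cycles)
    s = weights.sum()
    return weights / s if s > 0 else weights


def simulate_experiment(config: SimConfig
                        ) -> tuple[OtuTable, SampleSheet, TaxonomyTable, SimTruth]:
    """Draw one full mock experiment, deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    endo_ids = [f"OTU_endo_{i + 1:03d}" for i in range(config.n_endogenous_otus)]
    cont_ids = [f"OTU_cont_{i + 1:03d}" for i in range(config.n_contaminant_otus)]
    otu_ids = endo_ids + cont_ids
    n_otus = len(otu_ids)

    alpha = config.dirichlet_concentration
    group_comm = rng.dirichlet(np.full(config.n_endogenous_otus, alpha),
                               size=config.n_groups)
    contaminant_comm = rng.dirichlet(np.full(config.n_contaminant_otus, alpha))

    specimen_ids = [f"specimen_{i + 1}" for i in range(config.n_specimens)]
    control_ids = [f"control_{i + 1}" for i in range(config.n_controls)]
    groups = {s: f"group_{(i % config.n_groups) + 1}"
              for i, s in enumerate(specimen_ids)}

    pools = pd.DataFrame(0.0, index=specimen_ids + control_ids, columns=otu_ids)
    for i, s in enumerate(specimen_ids):
        g = i % config.n_groups
        pools.loc[s, endo_ids] = config.specimen_copies_per_ul * group_comm[g]
        # ambient contaminants reach specimens too, at control-level copies
        pools.loc[s, cont_ids] = config.control_copies_per_ul * contaminant_comm
    mean_specimen_pool = pools.loc[specimen_ids].mean(axis=0)
    for c in control_ids:
        pools.loc[c, cont_ids] = config.control_copies_per_ul * contaminant_comm
        # directed high->low biomass carryover during co-processing
        pools.loc[c] += config.carryover_fraction * mean_specimen_pool

    true_totals = pools.sum(axis=1)
    measured = true_totals * _lognormal_factors(rng, config.qpcr_cv,
                                                len(true_totals))

    efficiencies = rng.uniform(*config.pcr_efficiency_range, size=n_otus)
    counts = np.zeros((len(pools), n_otus), dtype=np.int64)
    for i, sid in enumerate(pools.index):
        comp = pools.loc[sid].to_numpy() / true_totals[sid]
        if config.apply_pcr:
            comp = apply_pcr_bias(comp, config.pcr_cycles, efficiencies)
        counts[i] = rng.multinomial(config.read_depth, comp)

    table = OtuTable(counts, list(pools.index), otu_ids)
    sheet_rows = []
    for s in specimen_ids:
        sheet_rows.append({"sample_id": s, "role": "specimen",
                           "group": groups[s],
                           "qpcr_copies_per_ul": float(measured[s]),
                           "pair_key": "", "description": "simulated specimen"})
    for c in control_ids:
        sheet_rows.append({"sample_id": c, "role": "control",
                           "group": "control",
                           "qpcr_copies_per_ul": float(measured[c]),
                           "pair_key": "", "description": "simulated control"})
    sheet = SampleSheet(pd.DataFrame(sheet_rows))

    tax_rows = []
    for j, o in enumerate(otu_ids):
        origin = "Endogenibacter" if o in set(endo_ids) else "Contaminarius"
        tax_rows.append({
            "otu_id": o, "lineage": "", "confidence": 1.0, "is_organelle": False,
            "domain": "Bacteria", "phylum": f"Phylum_{origin}",
            "class": f"Class_{origin}", "order": f"Order_{origin}",
            "family": f"Family_{origin}", "genus": f"{origin}_{j + 1:03d}",
        })
    tax = TaxonomyTable(pd.DataFrame(tax_rows))

    truth = SimTruth(
        origin=pd.Series({o: ("endogenous" if o in set(endo_ids) else "contaminant")
                          for o in otu_ids}),
        true_pools=pools,
        true_totals=true_totals,
        group_communities=pd.DataFrame(
            group_comm, index=[f"group_{g + 1}" for g in range(config.n_groups)],
            columns=endo_ids),
        contaminant_community=pd.Series(contaminant_comm, index=cont_ids),
    )
    return table, sheet, tax, truth


# ---------------------------------------------------------------------------
# FASTQ emission (exercises the QC stage end to end)
# ---------------------------------------------------------------------------

_BASES = "ACGT"


def tag_for_otu(otu_id: str, length: int = 245) -> str:
    """Deterministic pseudo-random tag sequence identifying an OTU.

    Derived from a SHA-256 stream over the id, so it is stable across
    processes and needs no seed.
    """
    out = []
    counter = 0
    while len(out) < length:
        digest = hashlib.sha256(f"{otu_id}:{counter}".encode()).digest()
        out.extend(_BASES[b & 3] for b in digest)
        counter += 1
    return "".join(out[:length])


def generate_reads(table: OtuTable, read_length: int = 245,
                   quality: int = 35, fail_fraction: float = 0.0,
                   seed: int = 0) -> dict[str, list[QualRead]]:
    """One read per table count, tagged by OTU; a ``fail_fraction`` of reads
    is deliberately made to fail QC (half too short, half low-quality)."""
    if not 0.0 <= fail_fraction <= 1.0:
        raise ConfigurationError("fail_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    tags = {o: tag_for_otu(o, read_length) for o in table.otu_ids}
    out: dict[str, list[QualRead]] = {}
    for i, sid in enumerate(table.sample_ids):
        reads: list[QualRead] = []
        k = 0
        for j, oid in enumerate(table.otu_ids):
            for _ in range(int(table.counts[i, j])):
                k += 1
                rid = f"{sid}_read{k}"
                bases, quals = tags[oid], (quality,) * read_length
                if fail_fraction and rng.random() < fail_fraction:
                    if rng.random() < 0.5:  # too short
                        n = max(1, read_length - 45)
                        bases, quals = bases[:n], quals[:n]
                    else:  # low quality: EE far above 1
                        quals = (12,) * read_length
                reads.append(QualRead(rid, bases, quals))
        out[sid] = reads
    return out


def emit_fastq(table: OtuTable, out_dir, read_length: int = 245,
               quality: int = 35, fail_fraction: float = 0.0,
               seed: int = 0) -> dict[str, Path]:
    """Write one FASTQ per sample; returns sample -> path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    per_sample = generate_reads(table, read_length, quality, fail_fraction, seed)
    paths = {}
    for sid, reads in per_sample.items():
        path = out_dir / f"{sid}.fastq"
        write_fastq(reads, path)
        paths[sid] = path
    return paths


def tally_reads(reads_by_sample: dict[str, list[QualRead]],
                otu_ids: list[str], tag_length: int = 245) -> OtuTable:
    """Rebuild an OTU table from tagged reads (inverse of read emission).

    Reads are matched on their first ``tag_length`` bases against each OTU's
    tag prefix; unmatched reads are ignored.
    """
    prefix = {tag_for_otu(o, tag_length): o for o in otu_ids}
    pos = {o: j for j, o in enumerate(otu_ids)}
    sample_ids = list(reads_by_sample)
    counts = np.zeros((len(sample_ids), len(otu_ids)), dtype=np.int64)
    for i, sid in enumerate(sample_ids):
        for read in reads_by_sample[sid]:
            oid = prefix.get(read.bases[:tag_length])
            if oid is not None:
                counts[i, pos[oid]] += 1
    return OtuTable(counts, sample_ids, otu_ids)


# ---------------------------------------------------------------------------
# random tree
# ---------------------------------------------------------------------------

def simulate_tree(otu_ids: list[str], seed: int = 0,
                  branch_scale: float = 0.1) -> skbio.TreeNode:
    """Random rooted binary tree with exponential branch lengths.

    Built by coalescent-style random joins, so every requested OTU is a tip;
    deterministic given the seed.
    """
    if len(otu_ids) < 2:
        raise ConfigurationError("a tree needs at least two OTUs")
    rng = np.random.default_rng(seed)
    nodes = []
    for o in otu_ids:
        tip = skbio.TreeNode(name=o)
        tip.length = float(rng.exponential(branch_scale))
        nodes.append(tip)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = skbio.TreeNode(children=[a, b])
        parent.length = float(rng.exponential(branch_scale))
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root
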