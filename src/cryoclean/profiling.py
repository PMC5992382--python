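"""Community-profile construction: rarefaction, organelle removal, taxonomy
collapsing, relative abundance, and major-taxon selection.

Rarefaction subsamples each library without replacement to a common depth
(multivariate hypergeometric draw), removing library-size effects before any
cross-sample comparison. Collapsing sums OTU counts sharing a rank label;
an OTU whose label was confidence-masked aggregates under
``unclassified_<next resolved rank>``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .model import (
    ConfigurationError,
    OtuTable,
    Profile,
    TaxonomyTable,
    ValidationError,
)

__all__ = ["rarefy", "remove_organelles", "collapse_taxonomy",
           "select_major_taxa", "heatmap_matrix"]

log = logging.getLogger("cryoclean")


def rarefy(table: OtuTable, depth: int, seed: int,
           drop_shallow: bool = True) -> OtuTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples whose total is below ``depth`` are dropped with a warning (or
    raise when ``drop_shallow=False``). Deterministic for a given seed; a
    sample whose total equals ``depth`` is returned unchanged (exhaustive
    draw).
    """
    if depth <= 0:
        raise ConfigurationError(f"rarefaction depth must be positive, got {depth}")
    totals = table.counts.sum(axis=1)
    shallow = [s for s, t in zip(table.sample_ids, totals) if t < depth]
    if shallow:
        if not drop_shallow:
            raise ConfigurationError(
                f"sample(s) {shallow} have fewer than {depth} reads; "
                "lower the rarefaction depth or drop them"
            )
        log.warning("rarefy: dropping %d sample(s) below depth %d: %s",
                    len(shallow), depth, shallow)
    keep = [s for s in table.sample_ids if s not in set(shallow)]
    if not keep:
        raise ConfigurationError(
            f"no sample reaches rarefaction depth {depth}"
        )
    sub = table.select_samples(keep)
    rng = np.random.default_rng(seed)
    out = np.empty_like(sub.counts)
    for i in range(sub.counts.shape[0]):
        out[i] = rng.multivariate_hypergeometric(sub.counts[i], depth)
    return OtuTable(out, sub.sample_ids, sub.otu_ids)


def remove_organelles(table: OtuTable, tax: TaxonomyTable) -> OtuTable:
    """Drop mitochondrial and chloroplastic OTUs; counts otherwise untouched."""
    tax.require_cover(table.otu_ids)
    organelles = set(tax.organelle_otus()) & set(table.otu_ids)
    if not organelles:
        return table
    out = table.drop_otus(organelles)
    log.info("remove_organelles: dropped %d organellar OTU(s)", len(organelles))
    if not out.otu_ids:
        log.warning("remove_organelles: every OTU was organellar; table is empty")
    return out


def collapse_taxonomy(table: OtuTable, tax: TaxonomyTable,
                      rank: str = "genus") -> Profile:
    """Sum counts of OTUs sharing a rank label, then convert to proportions.

    Per-sample totals are conserved by the collapse; proportions are taken
    afterwards (empty samples are flagged rather than divided by zero).
    """
    tax.require_cover(table.otu_ids)
    labels = [tax.label(o, rank) for o in table.otu_ids]
    df = table.to_dataframe()
    collapsed = df.T.groupby(pd.Index(labels, name=rank), sort=True).sum().T
    totals = collapsed.sum(axis=1).astype(float)
    empty = frozenset(collapsed.index[totals == 0])
    safe = totals.replace(0, 1.0)
    rel = collapsed.div(safe, axis=0)
    return Profile(rel_abund=rel, counts=collapsed, empty_samples=empty)


def select_major_taxa(profile: Profile, threshold: float,
                      scope: str = "any_sample",
                      comparator: str = ">=") -> list[str]:
    """Taxa whose proportion meets ``threshold`` under the scope rule.

    ``comparator`` is ``">="`` (the 1.0% rule) or ``">"`` (the 0.1% rule);
    ``scope`` is ``any_sample`` or ``all_samples``. Results are ordered by
    descending mean abundance, ties broken lexicographically by taxon id.
    """
    if not 0.0 < threshold < 1.0:
        raise ConfigurationError(f"threshold must lie in (0, 1), got {threshold}")
    if scope not in ("any_sample", "all_samples"):
        raise ConfigurationError(f"unknown scope {scope!r}")
    if comparator not in (">=", ">"):
        raise ConfigurationError(f"unknown comparator {comparator!r}")
    rel = profile.rel_abund
    if rel.empty:
        return []
    hits = rel.ge(threshold) if comparator == ">=" else rel.gt(threshold)
    mask = hits.any(axis=0) if scope == "any_sample" else hits.all(axis=0)
    selected = rel.columns[mask]
    means = rel[selected].mean(axis=0)
    order = sorted(selected, key=lambda t: (-means[t], t))
    log.info("select_major_taxa: %d taxa at %s%s (%s)", len(order),
             comparator, threshold, scope)
    return order


def heatmap_matrix(table: OtuTable, depth: int,
                   min_fraction: float = 0.01) -> pd.DataFrame:
    """Counts per OTU per ``depth`` sequences for abundant OTUs.

    Requires a table already rarefied to ``depth`` and keeps OTUs strictly
    exceeding ``min_fraction`` of the depth in at least one sample (at depth
    30,000 with the default 1.0% fraction: OTUs with >300 reads somewhere).
    """
    totals = table.counts.sum(axis=1)
    if not np.all(totals == depth):
        bad = [s for s, t in zip(table.sample_ids, totals) if t != depth]
        raise ValidationError(
            f"heatmap_matrix expects a table rarefied to {depth}; "
            f"sample(s) {bad} have different totals"
        )
    cutoff = min_fraction * depth
    df = table.to_dataframe()
    keep = df.columns[(df > cutoff).any(axis=0)]
    return df[list(keep)]
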