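"""Core data model for low-biomass amplicon decontamination pipelines.

The central objects are the OTU count table (samples x OTUs), the sample
sheet carrying roles (specimen vs background control) and qPCR biomass, the
taxonomy table with classifier confidences and organelle flags, and light
result containers for ordinations, dendrograms and permutation tests.
Everything downstream (QC, rarefaction, R-OTU decontamination, community
statistics) operates on these types.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CryocleanError",
    "FormatError",
    "ValidationError",
    "ConfigurationError",
    "RANKS",
    "OtuTable",
    "SampleSheet",
    "TaxonomyTable",
    "Profile",
    "ROtuReport",
    "Ordination",
    "Dendrogram",
    "TestResult",
]


class CryocleanError(Exception):
    """Base class for all package errors."""


class FormatError(CryocleanError):
    """A file could not be parsed in the expected dialect."""


class ValidationError(CryocleanError):
    """Parsed data violates a type invariant."""


class ConfigurationError(CryocleanError):
    """A parameter or experimental design is infeasible."""


#: Taxonomic ranks recognised in lineages, root-most first.
RANKS = ("domain", "phylum", "class", "order", "family", "genus")

#: Label used for ranks that could not be confidently assigned.
UNCLASSIFIED = "unclassified"


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} id: {i!r}")
        seen.add(i)
    return ids


class OtuTable:
    """Non-negative integer read counts over (samples x OTUs).

    Parameters
    ----------
    counts
        Matrix of shape (n_samples, n_otus); must be non-negative integers.
    sample_ids, otu_ids
        Unique, opaque, case-sensitive identifiers for rows and columns.
    """

    def __init__(self, counts, sample_ids: Sequence[str], otu_ids: Sequence[str]):
        self.sample_ids = _check_unique(sample_ids, "sample")
        self.otu_ids = _check_unique(otu_ids, "OTU")
        arr = np.asarray(counts)
        if arr.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValidationError(
                f"count matrix shape {arr.shape} does not match "
                f"({len(self.sample_ids)} samples, {len(self.otu_ids)} OTUs)"
            )
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                bad = np.argwhere(np.mod(arr, 1) != 0)[0]
                raise ValidationError(
                    f"non-integer count at sample {self.sample_ids[bad[0]]!r}, "
                    f"OTU {self.otu_ids[bad[1]]!r}"
                )
        arr = arr.astype(np.int64) if arr.size else arr.reshape(arr.shape).astype(np.int64)
        if arr.size and arr.min() < 0:
            bad = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count at sample {self.sample_ids[bad[0]]!r}, "
                f"OTU {self.otu_ids[bad[1]]!r}"
            )
        self.counts = arr

    # ---- construction / conversion -------------------------------------

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "OtuTable":
        """Build from a samples-as-rows DataFrame (index=samples, columns=OTUs)."""
        return cls(df.to_numpy(), list(df.index), list(df.columns))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts.copy(), index=list(self.sample_ids),
                            columns=list(self.otu_ids))

    # ---- basic queries --------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_totals(self) -> pd.Series:
        return pd.Series(self.counts.sum(axis=1), index=list(self.sample_ids))

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, OtuTable)
            and self.sample_ids == other.sample_ids
            and self.otu_ids == other.otu_ids
            and np.array_equal(self.counts, other.counts)
        )

    def __repr__(self) -> str:
        return f"OtuTable({len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs)"

    # ---- manipulation ---------------------------------------------------

    def select_samples(self, sample_ids: Sequence[str]) -> "OtuTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return OtuTable(self.counts[idx], list(sample_ids), self.otu_ids)

    def select_otus(self, otu_ids: Sequence[str]) -> "OtuTable":
        pos = {o: j for j, o in enumerate(self.otu_ids)}
        idx = [pos[o] for o in otu_ids]
        return OtuTable(self.counts[:, idx], self.sample_ids, list(otu_ids))

    def drop_otus(self, otu_ids: Iterable[str]) -> "OtuTable":
        drop = set(otu_ids)
        keep = [o for o in self.otu_ids if o not in drop]
        return self.select_otus(keep)

    def relative_abundance(self) -> "Profile":
        """Per-sample proportions at the OTU level (empty samples flagged)."""
        totals = self.counts.sum(axis=1, keepdims=True).astype(float)
        empty = totals[:, 0] == 0
        safe = np.where(totals == 0, 1.0, totals)
        rel = self.counts / safe
        return Profile(
            rel_abund=pd.DataFrame(rel, index=list(self.sample_ids),
                                   columns=list(self.otu_ids)),
            counts=self.to_dataframe(),
            empty_samples=frozenset(np.asarray(self.sample_ids)[empty]),
        )


ROLE_SPECIMEN = "specimen"
ROLE_CONTROL = "control"
VALID_ROLES = frozenset({ROLE_SPECIMEN, ROLE_CONTROL})


class SampleSheet:
    """Per-sample metadata: role, group, qPCR biomass, original/pre-amplified pairing.

    ``qpcr_copies_per_ul`` is the 16S rRNA gene copy number per microliter of
    DNA extract, the biomass proxy that converts relative abundances into
    cross-sample-comparable "absolute" abundances.
    """

    REQUIRED = ("sample_id", "role", "group", "qpcr_copies_per_ul")

    def __init__(self, df: pd.DataFrame):
        for col in self.REQUIRED:
            if col not in df.columns:
                raise FormatError(f"sample sheet is missing required column {col!r}")
        df = df.copy()
        df["sample_id"] = df["sample_id"].astype(str)
        _check_unique(list(df["sample_id"]), "sample")
        bad_roles = set(df["role"]) - VALID_ROLES
        if bad_roles:
            raise ValidationError(
                f"unknown sample role(s) {sorted(bad_roles)}; "
                f"expected one of {sorted(VALID_ROLES)}"
            )
        q = df["qpcr_copies_per_ul"]
        if q.isna().any():
            missing = df.loc[q.isna(), "sample_id"].tolist()
            raise ValidationError(
                f"empty qPCR value for sample(s) {missing}; record an explicit 0 "
                "or remove the sample from the sheet"
            )
        df["qpcr_copies_per_ul"] = q.astype(float)
        if (df["qpcr_copies_per_ul"] < 0).any():
            bad = df.loc[df["qpcr_copies_per_ul"] < 0, "sample_id"].tolist()
            raise ValidationError(f"negative qPCR value for sample(s) {bad}")
        if "pair_key" not in df.columns:
            df["pair_key"] = ""
        if "description" not in df.columns:
            df["description"] = ""
        df["pair_key"] = df["pair_key"].fillna("").astype(str)
        df["description"] = df["description"].fillna("").astype(str)
        self.df = df.set_index("sample_id", drop=False)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    def specimens(self) -> list[str]:
        return list(self.df.index[self.df["role"] == ROLE_SPECIMEN])

    def controls(self) -> list[str]:
        return list(self.df.index[self.df["role"] == ROLE_CONTROL])

    def qpcr(self) -> pd.Series:
        return self.df["qpcr_copies_per_ul"]

    def groups(self) -> pd.Series:
        return self.df["group"].astype(str)

    def require_cover(self, sample_ids: Iterable[str]) -> None:
        missing = [s for s in sample_ids if s not in self.df.index]
        if missing:
            raise ValidationError(f"sample sheet has no entry for sample(s) {missing}")

    def require_roles(self) -> None:
        if not self.specimens() or not self.controls():
            raise ConfigurationError(
                "decontamination requires at least one specimen and one control sample"
            )

    def __eq__(self, other) -> bool:
        return isinstance(other, SampleSheet) and self.df.equals(other.df)


class TaxonomyTable:
    """Ranked lineages with classifier confidence and organelle flags.

    The table stores the post-masking lineage: any rank whose confidence fell
    below the configured threshold is already replaced by ``unclassified``.
    """

    def __init__(self, df: pd.DataFrame):
        needed = {"otu_id", "confidence", "is_organelle", *RANKS}
        missing = needed - set(df.columns)
        if missing:
            raise FormatError(f"taxonomy table is missing column(s) {sorted(missing)}")
        df = df.copy()
        df["otu_id"] = df["otu_id"].astype(str)
        _check_unique(list(df["otu_id"]), "OTU")
        conf = df["confidence"].astype(float)
        if ((conf < 0) | (conf > 1)).any():
            bad = df.loc[(conf < 0) | (conf > 1), "otu_id"].tolist()
            raise ValidationError(f"confidence outside [0, 1] for OTU(s) {bad}")
        df["confidence"] = conf
        df["is_organelle"] = df["is_organelle"].astype(bool)
        self.df = df.set_index("otu_id", drop=False)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.df.index)

    def require_cover(self, otu_ids: Iterable[str]) -> None:
        missing = [o for o in otu_ids if o not in self.df.index]
        if missing:
            raise ValidationError(f"taxonomy has no record for OTU(s) {missing}")

    def organelle_otus(self) -> list[str]:
        return list(self.df.index[self.df["is_organelle"]])

    def label(self, otu_id: str, rank: str) -> str:
        """Collapse label for an OTU at ``rank``.

        A masked/unresolved rank is reported as ``unclassified_<R>`` where
        ``<R>`` is the nearest resolved ancestor rank value (mirroring the
        "unclassified genus within family X" convention), or plain
        ``unclassified`` when nothing resolves.
        """
        if rank not in RANKS:
            raise ConfigurationError(f"unknown rank {rank!r}; expected one of {RANKS}")
        row = self.df.loc[otu_id]
        value = str(row[rank])
        if value and value != UNCLASSIFIED:
            return value
        for parent in reversed(RANKS[: RANKS.index(rank)]):
            pval = str(row[parent])
            if pval and pval != UNCLASSIFIED:
                return f"{UNCLASSIFIED}_{pval}"
        return UNCLASSIFIED

    def __eq__(self, other) -> bool:
        return isinstance(other, TaxonomyTable) and self.df.equals(other.df)


@dataclass
class Profile:
    """Relative-abundance profile over samples x taxa (OTU- or rank-level).

    ``rel_abund`` rows sum to 1 (within 1e-9) except for samples listed in
    ``empty_samples``; ``counts`` keeps the pre-normalisation integers when
    known, so collapse conservation can be checked.
    """

    rel_abund: pd.DataFrame
    counts: pd.DataFrame | None = None
    empty_samples: frozenset = frozenset()

    def __post_init__(self):
        arr = self.rel_abund.to_numpy(dtype=float)
        if arr.size:
            if arr.min() < 0 or arr.max() > 1 + 1e-12:
                raise ValidationError("profile proportions must lie in [0, 1]")
            sums = arr.sum(axis=1)
            for sid, s in zip(self.rel_abund.index, sums):
                if sid in self.empty_samples:
                    continue
                if abs(s - 1.0) > 1e-9:
                    raise ValidationError(
                        f"proportions for sample {sid!r} sum to {s}, not 1"
                    )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.rel_abund.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.rel_abund.columns)

    def sample_vector(self, sample_id: str) -> pd.Series:
        return self.rel_abund.loc[sample_id]


@dataclass
class ROtuReport:
    """Per-OTU contaminant scoring and per-sample retention accounting.

    ``scores`` is indexed by OTU id with columns ``mean_abs_control``,
    ``mean_abs_specimen``, ``r_otu`` and ``is_contaminant``; ``r_otu`` is the
    ratio of mean qPCR-scaled abundance in background controls to that in
    specimens (0 when absent from controls, +inf when absent from specimens
    but present in controls). ``retention`` is filled by the removal step.
    """

    scores: pd.DataFrame
    threshold: float = 0.01
    retention: pd.DataFrame | None = None

    def contaminants(self) -> list[str]:
        return list(self.scores.index[self.scores["is_contaminant"]])


@dataclass
class Ordination:
    """Principal-coordinates embedding of a sample distance matrix."""

    sample_ids: list[str]
    coordinates: np.ndarray  # samples x positive axes
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives reported)
    proportion_explained: np.ndarray  # over positive eigenvalues only

    def __post_init__(self):
        if self.proportion_explained.size and self.proportion_explained.sum() > 1 + 1e-9:
            raise ValidationError("proportion_explained sums above 1")


@dataclass
class Dendrogram:
    """UPGMA merge sequence; ``merges`` items are (members_a, members_b, height)."""

    leaf_ids: list[str]
    merges: list[tuple[frozenset, frozenset, float]]

    @property
    def heights(self) -> list[float]:
        return [h for _, _, h in self.merges]

    def to_newick(self) -> str:
        node: dict[frozenset, tuple[str, float]] = {
            frozenset([l]): (l, 0.0) for l in self.leaf_ids
        }
        rep = ""
        for a, b, h in self.merges:
            (na, ha), (nb, hb) = node.pop(a), node.pop(b)
            rep = f"({na}:{h - ha:.10g},{nb}:{h - hb:.10g})"
            node[a | b] = (rep, h)
        if len(self.leaf_ids) == 1:
            rep = self.leaf_ids[0]
        return rep + ";"


@dataclass
class TestResult:
    """Outcome of a permutation or t test.

    For one-sided permutation tests the p-value uses the +1 correction:
    p = (#{permuted statistic >= observed} + 1) / (permutations + 1); the
    two-sided Mantel variant applies the same rule to |r|. Exhaustive
    enumerations divide the plain count by the number of enumerated
    permutations (the identity is included in the enumeration).
    """

    statistic: float
    p_value: float
    permutations: int
    seed: int | None = None
    method: str = ""

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0) and not np.isnan(self.p_value):
            raise ValidationError(f"p-value {self.p_value} outside [0, 1]")
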