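"""Canonical in-memory data model for optical-map SV calling.

All internal coordinates are 0-based, half-open, in base pairs.  On-disk
formats (BNX/CMAP/XMAP/BED) keep their native conventions; conversion happens
exactly once, inside the readers and writers.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional


@dataclass
class MoleculeTruth:
    """Provenance of a simulated molecule (absent for real data)."""

    haplotype: int
    chromosome: str
    start: float
    end: float
    orientation: str  # "+" or "-"
    alpha: float = 1.0  # realized per-molecule stretch factor


@dataclass
class MoleculeMap:
    """One imaged DNA molecule: backbone length and ordered label positions.

    ``labels`` holds the internal (fluorescent) label positions in bp from the
    molecule start, strictly increasing, each in [0, length).  The molecule
    ends themselves act as two artificial boundary labels and are not stored
    in ``labels``.
    """

    molecule_id: int
    length: float
    labels: list[float]
    truth: Optional[MoleculeTruth] = None

    def __post_init__(self) -> None:
        labs = list(self.labels)
        if any(b <= a for a, b in zip(labs, labs[1:])):
            labs = sorted(set(labs))
        self.labels = labs

    @property
    def n_labels(self) -> int:
        return len(self.labels)


@dataclass
class ReferenceContig:
    name: str
    length: float
    sites: list[float]

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.sites, self.sites[1:])):
            raise ValueError(f"contig {self.name}: site positions not strictly increasing")
        if self.sites and self.sites[-1] >= self.length:
            raise ValueError(f"contig {self.name}: site beyond contig length")


@dataclass
class ReferenceMap:
    """Per-chromosome ordered nicking-site positions from in silico digestion."""

    contigs: dict[str, ReferenceContig] = field(default_factory=dict)

    def add(self, contig: ReferenceContig) -> None:
        self.contigs[contig.name] = contig

    def __getitem__(self, name: str) -> ReferenceContig:
        return self.contigs[name]

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def __iter__(self):
        return iter(self.contigs.values())

    def __len__(self) -> int:
        return len(self.contigs)

    def total_sites(self) -> int:
        return sum(len(c.sites) for c in self.contigs.values())


@dataclass
class AlignmentRecord:
    """One molecule-to-reference alignment.

    ``pairs`` maps molecule label indices to reference site indices; both
    coordinates are monotone increasing for forward alignments, and molecule
    indices decrease while reference indices increase for reverse ones (the
    pair list is always stored in reference order).  ``cigar`` is over
    {M, D, I}: M a matched label/site pair, D a reference site with no
    molecule label, I a molecule label with no reference site.
    """

    molecule_id: int
    chromosome: str
    ref_start: float
    ref_end: float
    orientation: str  # "+" or "-"
    pairs: list[tuple[int, int]]
    cigar: str
    confidence: float
    source: str = "builtin"

    def __post_init__(self) -> None:
        if self.orientation not in ("+", "-"):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.confidence < 0:
            raise ValueError("confidence must be >= 0")
        if self.cigar.count("M") != len(self.pairs):
            raise ValueError("cigar M count inconsistent with pair count")

    @property
    def n_matched(self) -> int:
        return len(self.pairs)


@dataclass
class SplitAlignment:
    """A molecule aligned as >=1 segments over disjoint molecule label ranges."""

    molecule_id: int
    segments: list[AlignmentRecord]


@dataclass
class MaskRegion:
    chromosome: str
    start: float
    end: float
    mask_class: str  # n_gap | fragile_site | pseudo_autosomal | ultra_dense

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("mask region start must be < end")


#: SV types emitted by the three calling modules.
SV_TYPES = (
    "insertion",
    "deletion",
    "missing_site",
    "extra_site",
    "inversion_medium",
    "inversion_large",
    "translocation_intra",
    "translocation_inter",
    "cnv_gain",
    "cnv_loss",
)


@dataclass
class SVCall:
    """A typed, zygosity-annotated variant call."""

    chromosome: str
    start: float
    end: float
    sv_type: str
    zygosity: str  # hom | het | na
    size: float  # signed bp change estimate; 0 when not applicable
    support: int  # supporting molecules (m or cluster size)
    coverage: int  # molecules covering the locus (M)
    p_value: float
    likelihood_ratio: float  # null over best alternative; smaller = stronger
    module: str  # site | size | complex
    info: dict = field(default_factory=dict)

    def overlaps(self, chrom: str, start: float, end: float) -> bool:
        return self.chromosome == chrom and self.start < end and start < self.end
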