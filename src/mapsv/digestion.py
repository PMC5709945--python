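"""In silico digestion of a reference sequence into a nicking-site map.

A nicking enzyme (default Nt.BspQI, motif GCTCTTC) cuts one strand wherever
its recognition motif occurs; fluorescent labels mark the nick positions.
Sites are found on both strands of the reference and then merged at the
imaging-resolution scale: adjacent sites closer than ``d_half`` — the
distance at which two labels merge with probability one half in the
stochastic imaging model — are deterministically collapsed to their midpoint,
so the reference map matches what the instrument could at best resolve.
"""
from __future__ import annotations

import re
from dataclasses import dataclass

from .core import ReferenceContig, ReferenceMap

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class DigestionParams:
    motif: str = "GCTCTTC"
    nick_offset: int = 0
    d_half: float = 1500.0

    def __post_init__(self) -> None:
        if not self.motif:
            raise ValueError("motif must be non-empty")
        if self.d_half <= 0:
            raise ValueError("d_half must be positive")
        for ch in self.motif.upper():
            if ch not in IUPAC:
                raise ValueError(f"non-IUPAC character {ch!r} in motif")


def _motif_regex(motif: str) -> re.Pattern:
    # Character classes over ACGT only, so matches never overlap N runs.
    return re.compile("".join(f"[{IUPAC[ch]}]" for ch in motif.upper()))


def find_nick_sites(sequence: str, params: DigestionParams) -> list[float]:
    """Positions (bp, 0-based) of nick sites on both strands of ``sequence``.

    A forward-strand motif occurrence at p nicks at p + nick_offset; an
    occurrence of the motif's reverse complement at p mirrors the offset and
    nicks at p + len(motif) - 1 - nick_offset.  Output is sorted and
    deduplicated.
    """
    seq = sequence.upper()
    motif = params.motif.upper()
    L = len(motif)
    fwd = _motif_regex(motif)
    rev = _motif_regex(reverse_complement(motif))
    sites: set[float] = set()
    for m in fwd.finditer(seq):
        sites.add(float(m.start() + params.nick_offset))
    for m in rev.finditer(seq):
        sites.add(float(m.start() + L - 1 - params.nick_offset))
    return sorted(sites)


def merge_close_labels(positions: list[float], d_half: float) -> list[float]:
    """Deterministically merge adjacent labels closer than ``d_half``.

    Each too-close pair is replaced by its midpoint, left to right, re-checking
    against earlier labels after every merge until stable.  The result has all
    adjacent gaps >= d_half and the operation is idempotent.
    """
    merged: list[float] = []
    for pos in positions:
        merged.append(pos)
        while len(merged) >= 2 and merged[-1] - merged[-2] < d_half:
            b = merged.pop()
            a = merged.pop()
            merged.append((a + b) / 2.0)
    return merged


def digest_sequence(sequence: str, params: DigestionParams | None = None) -> list[float]:
    params = params or DigestionParams()
    return merge_close_labels(find_nick_sites(sequence, params), params.d_half)


def digest(sequences: dict[str, str], params: DigestionParams | None = None) -> ReferenceMap:
    """Digest per-chromosome sequences into a resolution-merged ReferenceMap."""
    params = params or DigestionParams()
    refmap = ReferenceMap()
    for name, seq in sequences.items():
        refmap.add(ReferenceContig(name, float(len(seq)), digest_sequence(seq, params)))
    return refmap
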