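"""Readers and writers for the optical-mapping formats the pipeline touches.

Dialects follow the common public layouts of BNX 1.x (molecules), CMAP
(reference maps) and XMAP (alignments).  On-disk coordinates are 1-based for
CMAP/XMAP and converted to the internal 0-based half-open convention exactly
once here; BNX label positions are molecule-relative and used as-is.  Only the
columns the pipeline consumes are required.
"""
from __future__ import annotations

import io
import warnings
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .core import (
    AlignmentRecord,
    MaskRegion,
    MoleculeMap,
    MoleculeTruth,
    ReferenceContig,
    ReferenceMap,
    SVCall,
)


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> dict[str, str]:
    """Read a (possibly multi-record) FASTA into {name: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


# ---------------------------------------------------------------------------
# BNX molecules

_BNX_HEADER = "# BNX File Version: 1.2\n#0h\tLabelChannel\tMoleculeId\tLength\n#1h\tLabelChannel\tLabelPositions\n"


def write_molecules(molecules: list[MoleculeMap], path) -> None:
    with open(path, "w") as fh:
        fh.write(_BNX_HEADER)
        for mol in molecules:
            fh.write(f"0\t{mol.molecule_id}\t{mol.length:.1f}\n")
            fields = "\t".join(f"{p:.1f}" for p in mol.labels)
            fh.write("1" + ("\t" + fields if fields else "") + "\n")
            if mol.truth is not None:
                t = mol.truth
                fh.write(
                    f"#T\t{t.haplotype}\t{t.chromosome}\t{t.start:.1f}\t{t.end:.1f}"
                    f"\t{t.orientation}\t{t.alpha!r}\n"
                )


def read_molecules(path) -> list[MoleculeMap]:
    """Parse a BNX-style file into MoleculeMaps.

    Raises ParseError (naming the line number) on malformed blocks; unsorted
    label positions are repaired by sorting, with a warning.
    """
    molecules: list[MoleculeMap] = []
    current: MoleculeMap | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#T\t"):
                if current is None:
                    raise ParseError(f"line {lineno}: truth line outside a molecule block")
                f = line.split("\t")
                current.truth = MoleculeTruth(int(f[1]), f[2], float(f[3]), float(f[4]),
                                              f[5], float(f[6]) if len(f) > 6 else 1.0)
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "0":
                try:
                    current = MoleculeMap(int(fields[1]), float(fields[2]), [])
                except (IndexError, ValueError) as exc:
                    raise ParseError(f"line {lineno}: malformed molecule backbone line") from exc
                molecules.append(current)
            elif fields[0] == "1":
                if current is None:
                    raise ParseError(f"line {lineno}: label line without a preceding backbone line")
                try:
                    labels = [float(x) for x in fields[1:] if x != ""]
                except ValueError as exc:
                    raise ParseError(f"line {lineno}: malformed label position") from exc
                if any(b <= a for a, b in zip(labels, labels[1:])):
                    warnings.warn(
                        f"line {lineno}: unsorted label positions; repaired by sorting",
                        stacklevel=2,
                    )
                    labels = sorted(set(labels))
                current.labels = labels
    return molecules


# ---------------------------------------------------------------------------
# CMAP reference maps

_CMAP_COLS = ["CMapId", "ContigLength", "NumSites", "SiteID", "LabelChannel", "Position"]


def write_reference_cmap(refmap: ReferenceMap, path) -> None:
    rows = []
    for contig in refmap:
        n = len(contig.sites)
        for i, pos in enumerate(contig.sites, start=1):
            rows.append((contig.name, contig.length, n, i, 1, pos + 1.0))
        # conventional end-of-contig row on channel 0
        rows.append((contig.name, contig.length, n, n + 1, 0, contig.length))
    with open(path, "w") as fh:
        fh.write("#h " + "\t".join(_CMAP_COLS) + "\n")
        for r in rows:
            fh.write(f"{r[0]}\t{r[1]:.1f}\t{r[2]}\t{r[3]}\t{r[4]}\t{r[5]:.1f}\n")


def read_reference_cmap(path) -> ReferenceMap:
    df = pd.read_csv(
        path, sep="\t", comment="#", names=_CMAP_COLS,
        dtype={"CMapId": str},
    )
    refmap = ReferenceMap()
    for name, grp in df.groupby("CMapId", sort=False):
        grp_sites = grp[grp["LabelChannel"] != 0]
        if grp_sites["SiteID"].duplicated().any():
            raise ParseError(f"contig {name}: duplicate SiteID")
        positions = [p - 1.0 for p in grp_sites["Position"].tolist()]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ParseError(f"contig {name}: non-monotone site positions")
        refmap.add(ReferenceContig(str(name), float(grp["ContigLength"].iloc[0]), positions))
    return refmap


# ---------------------------------------------------------------------------
# CIGAR / hit-string helpers

def expand_hit_string(hit: str) -> str:
    """Expand a run-length hit string like '2M1D2M' into 'MMDMM'."""
    out = []
    num = ""
    for ch in hit:
        if ch.isdigit():
            num += ch
        elif ch in "MDI":
            out.append(ch * (int(num) if num else 1))
            num = ""
        else:
            raise ParseError(f"bad hit-string character {ch!r}")
    if num:
        raise ParseError("hit string ends with a dangling count")
    return "".join(out)


def compress_cigar(cigar: str) -> str:
    """Run-length encode an expanded CIGAR ('MMDMM' -> '2M1D2M')."""
    out = []
    i = 0
    while i < len(cigar):
        j = i
        while j < len(cigar) and cigar[j] == cigar[i]:
            j += 1
        out.append(f"{j - i}{cigar[i]}")
        i = j
    return "".join(out)


# ---------------------------------------------------------------------------
# XMAP alignments

_XMAP_COLS = [
    "XmapEntryID", "QryContigID", "RefContigID", "QryStartPos", "QryEndPos",
    "RefStartPos", "RefEndPos", "Orientation", "Confidence", "HitEnum",
    "Alignment", "Source",
]


def _pairs_to_alignment_string(pairs: list[tuple[int, int]]) -> str:
    return "".join(f"({j + 1},{i + 1})" for i, j in pairs)


def _alignment_string_to_pairs(s: str) -> list[tuple[int, int]]:
    pairs = []
    for tok in s.strip().strip("()").split(")("):
        if not tok:
            continue
        ref_id, qry_id = tok.split(",")
        pairs.append((int(qry_id) - 1, int(ref_id) - 1))
    return pairs


def write_alignments(alignments: list[AlignmentRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("#h " + "\t".join(_XMAP_COLS) + "\n")
        for k, rec in enumerate(alignments, start=1):
            mol_idx = [i for i, _ in rec.pairs]
            qry_start = min(mol_idx) + 1 if mol_idx else 1
            qry_end = max(mol_idx) + 1 if mol_idx else 1
            fh.write(
                "\t".join(
                    [
                        str(k), str(rec.molecule_id), rec.chromosome,
                        str(qry_start), str(qry_end),
                        f"{rec.ref_start + 1.0:.1f}", f"{rec.ref_end:.1f}",
                        rec.orientation, f"{rec.confidence:.2f}",
                        compress_cigar(rec.cigar),
                        _pairs_to_alignment_string(rec.pairs),
                        rec.source,
                    ]
                )
                + "\n"
            )


def read_alignments(path, dialect: str = "xmap") -> list[AlignmentRecord]:
    """Read alignments from an XMAP-style file or the equivalent plain TSV.

    Both dialects are normalized into AlignmentRecord so downstream modules
    are aligner-agnostic.
    """
    if dialect not in ("xmap", "oma_tsv"):
        raise ValueError(f"unknown alignment dialect {dialect!r}")
    records: list[AlignmentRecord] = []
    df = pd.read_csv(path, sep="\t", comment="#", names=_XMAP_COLS, dtype=str)
    for _, row in df.iterrows():
        orientation = row["Orientation"]
        if orientation not in ("+", "-"):
            raise ParseError(f"unknown orientation symbol {orientation!r}")
        if pd.isna(row["Confidence"]) or row["Confidence"] == "":
            warnings.warn("missing confidence; defaulting to 0", stacklevel=2)
            confidence = 0.0
        else:
            confidence = float(row["Confidence"])
        cigar = expand_hit_string(row["HitEnum"])
        pairs = _alignment_string_to_pairs(row["Alignment"])
        source = row["Source"] if isinstance(row["Source"], str) else "external"
        records.append(
            AlignmentRecord(
                molecule_id=int(row["QryContigID"]),
                chromosome=str(row["RefContigID"]),
                ref_start=float(row["RefStartPos"]) - 1.0,
                ref_end=float(row["RefEndPos"]),
                orientation=orientation,
                pairs=pairs,
                cigar=cigar,
                confidence=max(confidence, 0.0),
                source=source,
            )
        )
    return records


# ---------------------------------------------------------------------------
# BED masks

def read_masks(path, mask_class: str | None = None) -> list[MaskRegion]:
    """Read a BED file of mask regions (0-based half-open, as BED is).

    The mask class comes from the 4th column when present, else from
    ``mask_class``.
    """
    masks = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            cls = f[3] if len(f) > 3 else mask_class
            if cls is None:
                raise ParseError("mask class missing: no 4th BED column and no default given")
            masks.append(MaskRegion(f[0], float(f[1]), float(f[2]), cls))
    return masks


def write_masks(masks: list[MaskRegion], path) -> None:
    with open(path, "w") as fh:
        for m in masks:
            fh.write(f"{m.chromosome}\t{m.start:.0f}\t{m.end:.0f}\t{m.mask_class}\n")


# ---------------------------------------------------------------------------
# SV call tables

_SV_COLS = [
    "chromosome", "start", "end", "type", "zygosity", "size",
    "support", "coverage", "p_value", "likelihood_ratio", "module",
]


def write_sv_table(calls: list[SVCall], path) -> None:
    """Write SV calls as a 1-based inclusive TSV, sorted by (chromosome, start)."""
    rows = [
        {
            "chromosome": c.chromosome,
            "start": int(c.start) + 1,
            "end": int(c.end),
            "type": c.sv_type,
            "zygosity": c.zygosity,
            "size": c.size,
            "support": c.support,
            "coverage": c.coverage,
            "p_value": c.p_value,
            "likelihood_ratio": c.likelihood_ratio,
            "module": c.module,
        }
        for c in sorted(calls, key=lambda c: (c.chromosome, c.start, c.end))
    ]
    pd.DataFrame(rows, columns=_SV_COLS).to_csv(path, sep="\t", index=False)


def read_sv_table(path) -> list[SVCall]:
    df = pd.read_csv(path, sep="\t")
    calls = []
    for _, r in df.iterrows():
        calls.append(
            SVCall(
                chromosome=str(r["chromosome"]),
                start=float(r["start"]) - 1.0,
                end=float(r["end"]),
                sv_type=r["type"],
                zygosity=r["zygosity"],
                size=float(r["size"]),
                support=int(r["support"]),
                coverage=int(r["coverage"]),
                p_value=float(r["p_value"]),
                likelihood_ratio=float(r["likelihood_ratio"]),
                module=r["module"],
            )
        )
    return calls
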