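"""Generative model for single-molecule optical maps and mutated genomes.

The simulator has two layers.  The genome layer injects structural variants
(and nuisance SNVs/small indels) into a reference sequence, optionally
building a diploid with a controlled homozygous/heterozygous mix.  The
molecule layer then images each haplotype under the complete error model:

1. molecule starts uniform over the genome; length ``l0 + Poisson(mu_l)``;
2. each true nicking site drops out independently with probability ``f_minus``;
3. false-positive labels appear as a Poisson process at rate ``f_plus`` per bp;
4. a per-molecule stretch factor ``alpha ~ Cauchy(o_alpha, s_alpha)`` scales
   every inter-label distance;
5. adjacent labels at distance d merge to their midpoint with probability
   ``1 - 1/(1 + exp(-0.01 (d - d_half)))``;
6. each label moves by an offset uniform on [-e, e].

Molecule orientation is randomized, and each simulated molecule carries its
ground truth (haplotype, source interval, orientation) for evaluation.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import MoleculeMap, MoleculeTruth
from .digestion import DigestionParams, find_nick_sites, reverse_complement


# ---------------------------------------------------------------------------
# Parameters

@dataclass
class ErrorModelParams:
    """Full parameter set of the optical-map error model.

    Defaults emulate a current nanochannel system, set slightly above the
    roughly 10% label false-negative rate and one false-positive label per
    100 kbp seen in real data, so the callers are exercised on noisy input.
    """

    coverage: float = 100.0      # fold genome coverage (sets molecule count)
    l0: float = 150_000.0        # bp, minimum molecule length
    mu_l: float = 100_000.0      # bp, mean of the Poisson length excess
    f_minus: float = 0.12        # per-site false-negative probability
    f_plus: float = 1.2e-5       # per-bp false-positive label rate
    o_alpha: float = 1.0         # location of the Cauchy stretch factor
    s_alpha: float = 0.015       # scale of the Cauchy stretch factor
    d_half: float = 1500.0       # bp, distance with merge probability 1/2
    e: float = 50.0              # bp, half-width of the uniform label offset

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_minus <= 1.0:
            raise ValueError("f_minus must be in [0, 1]")
        if min(self.l0, self.mu_l, self.d_half, self.e) < 0 or self.f_plus < 0:
            raise ValueError("error-model rates and lengths must be non-negative")

    def n_molecules(self, genome_length: float) -> int:
        return int(round(self.coverage * genome_length / (self.l0 + self.mu_l)))


@dataclass
class DiploidParams:
    p_hom: float = 0.5   # chance a haplotype-1 variant is copied to haplotype 2
    p_het: float = 0.5   # chance a remaining het variant moves to haplotype 2

    def __post_init__(self) -> None:
        if not (0 <= self.p_hom <= 1 and 0 <= self.p_het <= 1):
            raise ValueError("p_hom and p_het must be in [0, 1]")


@dataclass
class TruthVariant:
    """One injected variant, recorded in reference coordinates."""

    kind: str            # snv|small_indel|insertion|deletion|inversion|translocation|cnv
    chromosome: str
    start: float
    end: float           # reference span; == start for pure insertions
    size: float
    zygosity: str = "hom"
    haplotypes: tuple[int, ...] = (1,)
    alt_seq: str = ""    # inserted sequence (insertions, small insertions, snv alt)
    target: float = -1.0  # paste position for translocations
    copies: int = 1      # total copy number for cnv (tandem duplication)

    def __post_init__(self) -> None:
        if self.kind not in (
            "snv", "small_indel", "insertion", "deletion", "inversion",
            "translocation", "cnv",
        ):
            raise ValueError(f"unknown variant kind {self.kind!r}")
        if self.zygosity == "hom" and self.haplotypes != (1, 2) and len(self.haplotypes) == 1:
            # haploid truth defaults to hom on haplotype 1
            pass


@dataclass
class VariantPlan:
    """Counts and size distributions of variants to inject.

    SV sizes are drawn log-uniformly from the given (lo, hi) ranges; loci are
    sampled uniformly, rejecting overlaps (with a spacing buffer) and N runs.
    SNVs and small indels are nuisance realism; SVs are the signal.
    """

    n_insertions: int = 0
    n_deletions: int = 0
    indel_size_range: tuple[float, float] = (2500.0, 10000.0)
    n_inversions: int = 0
    inversion_size_range: tuple[float, float] = (5000.0, 80000.0)
    n_translocations: int = 0
    translocation_size_range: tuple[float, float] = (50000.0, 150000.0)
    n_cnvs: int = 0
    cnv_size_range: tuple[float, float] = (100000.0, 300000.0)
    cnv_copies: int = 3
    n_snvs: int = 0
    n_small_indels: int = 0
    small_indel_size_range: tuple[float, float] = (1.0, 50.0)
    # minimum gap between injected SV loci: a few inter-site gaps, so that
    # no two SVs share defining nicking sites (such loci are not separately
    # resolvable from inter-site distances and would confound scoring)
    spacing: float = 50000.0
    edge_margin: float = 200000.0


# ---------------------------------------------------------------------------
# Genome helpers

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def random_genome(length: int, seed: int = 0, gc: float = 0.41) -> str:
    """A random i.i.d. genome with the given GC content (synthetic stand-in
    for a real reference chromosome)."""
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p).tobytes().decode()


def apply_variants(sequence: str, variants: Sequence[TruthVariant]) -> str:
    """Realize a truth list on ``sequence`` (reference coordinates).

    Edits are applied right to left so earlier coordinates stay valid; the
    output is exactly the mutated haplotype the truth list describes.
    """
    edits: list[tuple[float, int, str]] = []  # (pos, deleted_len, inserted_seq)
    for v in variants:
        s, e = int(v.start), int(v.end)
        if v.kind in ("insertion",):
            edits.append((s, 0, v.alt_seq))
        elif v.kind == "deletion":
            edits.append((s, e - s, ""))
        elif v.kind == "snv":
            edits.append((s, 1, v.alt_seq))
        elif v.kind == "small_indel":
            if v.alt_seq:
                edits.append((s, 0, v.alt_seq))
            else:
                edits.append((s, e - s, ""))
        elif v.kind == "inversion":
            edits.append((s, e - s, reverse_complement(sequence[s:e])))
        elif v.kind == "translocation":
            seg = sequence[s:e]
            edits.append((s, e - s, ""))
            edits.append((int(v.target), 0, seg))
        elif v.kind == "cnv":
            seg = sequence[s:e]
            edits.append((e, 0, seg * (v.copies - 1)))
    out = sequence
    for pos, dlen, ins in sorted(edits, key=lambda t: -t[0]):
        out = out[:pos] + ins + out[pos + dlen :]
    return out


def _sample_loci(
    rng: np.random.Generator,
    n: int,
    span_sampler,
    genome_len: int,
    taken: list[tuple[float, float]],
    spacing: float,
    edge_margin: float,
    sequence: str,
    max_tries: int = 10000,
) -> list[tuple[float, float]]:
    loci = []
    tries = 0
    while len(loci) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError("variant plan infeasible: cannot place without overlap")
        span = span_sampler()
        start = rng.uniform(edge_margin, genome_len - edge_margin - span)
        end = start + span
        if any(start - spacing < e and s < end + spacing for s, e in taken):
            continue
        if "N" in sequence[int(start) : int(end) + 1]:
            continue
        taken.append((start, end))
        loci.append((float(int(start)), float(int(end))))
    return loci


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def inject_variants(
    sequence: str,
    plan: VariantPlan,
    seed: int | np.random.Generator = 0,
    chromosome: str = "chr1",
) -> tuple[str, list[TruthVariant]]:
    """Inject the planned variants into ``sequence``; return the mutated
    sequence and the truth list (reference coordinates, haploid/hom)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = len(sequence)
    taken: list[tuple[float, float]] = []
    truth: list[TruthVariant] = []

    def rand_seq(n: int) -> str:
        return "".join(rng.choice(list("ACGT"), size=n))

    r = plan.indel_size_range
    for s, e in _sample_loci(rng, plan.n_deletions, lambda: _log_uniform(rng, *r),
                             L, taken, plan.spacing, plan.edge_margin, sequence):
        truth.append(TruthVariant("deletion", chromosome, s, e, e - s))
    for s, _ in _sample_loci(rng, plan.n_insertions, lambda: 1.0,
                             L, taken, plan.spacing, plan.edge_margin, sequence):
        size = int(_log_uniform(rng, *r))
        truth.append(TruthVariant("insertion", chromosome, s, s, size, alt_seq=rand_seq(size)))
    ri = plan.inversion_size_range
    for s, e in _sample_loci(rng, plan.n_inversions, lambda: _log_uniform(rng, *ri),
                             L, taken, plan.spacing, plan.edge_margin, sequence):
        truth.append(TruthVariant("inversion", chromosome, s, e, e - s))
    rt = plan.translocation_size_range
    for s, e in _sample_loci(rng, plan.n_translocations, lambda: _log_uniform(rng, *rt),
                             L, taken, plan.spacing, plan.edge_margin, sequence):
        (tgt, _), = _sample_loci(rng, 1, lambda: 1.0, L, taken,
                                 plan.spacing, plan.edge_margin, sequence)
        truth.append(TruthVariant("translocation", chromosome, s, e, e - s, target=tgt))
    rc = plan.cnv_size_range
    for s, e in _sample_loci(rng, plan.n_cnvs, lambda: _log_uniform(rng, *rc),
                             L, taken, plan.spacing, plan.edge_margin, sequence):
        truth.append(TruthVariant("cnv", chromosome, s, e, (e - s) * (plan.cnv_copies - 1),
                                  copies=plan.cnv_copies))
    rs = plan.small_indel_size_range
    for s, e in _sample_loci(rng, plan.n_small_indels, lambda: float(int(_log_uniform(rng, *rs))),
                             L, taken, 200.0, plan.edge_margin, sequence):
        if rng.random() < 0.5:
            truth.append(TruthVariant("small_indel", chromosome, s, e, e - s))
        else:
            size = max(1, int(e - s))
            truth.append(TruthVariant("small_indel", chromosome, s, s, size,
                                      alt_seq=rand_seq(size)))
    for s, _ in _sample_loci(rng, plan.n_snvs, lambda: 1.0, L, taken,
                             50.0, plan.edge_margin, sequence):
        ref_base = sequence[int(s)]
        alt = rng.choice([b for b in "ACGT" if b != ref_base])
        truth.append(TruthVariant("snv", chromosome, s, s + 1, 1, alt_seq=str(alt)))

    truth.sort(key=lambda v: v.start)
    return apply_variants(sequence, truth), truth


def build_diploid(
    haploid_truth: Sequence[TruthVariant],
    reference: str,
    params: DiploidParams,
    seed: int | np.random.Generator = 0,
    chromosome: str = "chr1",
) -> tuple[str, str, list[TruthVariant]]:
    """Distribute haploid variants over two haplotypes.

    Haplotype 1 starts as the mutated genome and haplotype 2 as the
    reference.  Each variant is copied to haplotype 2 with probability
    ``p_hom`` (making it homozygous); each variant left heterozygous moves to
    haplotype 2 with probability ``p_het``.  The total number of variant loci
    is preserved.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    annotated: list[TruthVariant] = []
    hap1: list[TruthVariant] = []
    hap2: list[TruthVariant] = []
    for v in haploid_truth:
        u = rng.random()
        if u < params.p_hom:
            zyg, haps = "hom", (1, 2)
        elif rng.random() < params.p_het:
            zyg, haps = "het", (2,)
        else:
            zyg, haps = "het", (1,)
        w = TruthVariant(v.kind, v.chromosome, v.start, v.end, v.size, zyg, haps,
                         v.alt_seq, v.target, v.copies)
        annotated.append(w)
        if 1 in haps:
            hap1.append(w)
        if 2 in haps:
            hap2.append(w)
    seq1 = apply_variants(reference, hap1)
    seq2 = apply_variants(reference, hap2)
    return seq1, seq2, annotated


# ---------------------------------------------------------------------------
# Molecule simulation

@dataclass
class HaplotypeMap:
    """Digested (unmerged) site positions of one haplotype, ready to image."""

    haplotype: int
    contigs: dict[str, tuple[float, np.ndarray]]  # name -> (length, sites)

    @classmethod
    def from_sequences(cls, haplotype: int, sequences: dict[str, str],
                       digestion: DigestionParams | None = None) -> "HaplotypeMap":
        digestion = digestion or DigestionParams()
        contigs = {
            name: (float(len(seq)), np.asarray(find_nick_sites(seq, digestion)))
            for name, seq in sequences.items()
        }
        return cls(haplotype, contigs)

    def total_length(self) -> float:
        return sum(length for length, _ in self.contigs.values())


def _draw_alpha(rng: np.random.Generator, o: float, s: float) -> float:
    """Per-molecule stretch factor; redraw pathological heavy-tail draws so
    physical distances stay positive (|alpha - o| capped at 10 s)."""
    if s == 0:
        return o
    while True:
        a = o + s * rng.standard_cauchy()
        if a > 0 and abs(a - o) <= 10 * s:
            return float(a)


def _stochastic_merge(labels: np.ndarray, d_half: float, rng: np.random.Generator) -> np.ndarray:
    if len(labels) < 2 or d_half <= 0:  # d_half = 0 disables resolution merging
        return labels
    merged = [labels[0]]
    for pos in labels[1:]:
        merged.append(pos)
        while len(merged) >= 2:
            d = merged[-1] - merged[-2]
            p_merge = 1.0 - 1.0 / (1.0 + np.exp(-0.01 * (d - d_half)))
            if rng.random() < p_merge:
                b = merged.pop()
                a = merged.pop()
                merged.append((a + b) / 2.0)
            else:
                break
    return np.asarray(merged)


def simulate_molecules(
    haplotypes: Sequence[HaplotypeMap],
    params: ErrorModelParams,
    seed: int | np.random.Generator = 0,
    n_molecules: int | None = None,
) -> list[MoleculeMap]:
    """Image ``n`` molecules from the given haplotypes under the error model.

    Molecules are drawn from each haplotype with equal probability, from a
    chromosome with probability proportional to its length, and in a random
    orientation.  Each MoleculeMap carries its ground truth.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if params.f_minus >= 1.0 and params.f_plus == 0.0:
        warnings.warn("f_minus=1 with f_plus=0: molecules will carry no internal labels")
    mean_len = params.l0 + params.mu_l
    genome_len = haplotypes[0].total_length()
    n = n_molecules if n_molecules is not None else params.n_molecules(genome_len)

    molecules: list[MoleculeMap] = []
    for mol_id in range(1, n + 1):
        hap = haplotypes[int(rng.integers(len(haplotypes)))]
        names = list(hap.contigs)
        lengths = np.array([hap.contigs[c][0] for c in names])
        chrom = names[int(rng.choice(len(names), p=lengths / lengths.sum()))]
        chrom_len, sites = hap.contigs[chrom]

        length = params.l0 + float(rng.poisson(params.mu_l))
        start = rng.uniform(0.0, chrom_len)
        end = min(start + length, chrom_len)
        length = end - start

        lo, hi = np.searchsorted(sites, [start, end])
        labels = sites[lo:hi] - start
        # per-site false negatives
        if params.f_minus > 0 and len(labels):
            labels = labels[rng.random(len(labels)) >= params.f_minus]
        # false positives: a Poisson process at f_plus per bp.  Drawing one
        # Poisson(L * f_plus) count with uniform placement is identical to
        # per-gap Poisson(d * f_plus) draws because the gaps (with the two
        # boundary pseudo-labels) tile the molecule.
        n_fp = rng.poisson(length * params.f_plus)
        if n_fp:
            labels = np.sort(np.concatenate([labels, rng.uniform(0.0, length, n_fp)]))
        # per-molecule stretch applied to every inter-label distance,
        # boundary pseudo-labels included, i.e. a uniform rescaling
        alpha = _draw_alpha(rng, params.o_alpha, params.s_alpha)
        labels = labels * alpha
        length = length * alpha
        # resolution-limited stochastic merging
        labels = _stochastic_merge(labels, params.d_half, rng)
        # measurement offsets, clipped inside the backbone and kept ordered
        if params.e > 0 and len(labels):
            labels = np.sort(np.clip(labels + rng.uniform(-params.e, params.e, len(labels)),
                                     1.0, length - 1.0))
        orientation = "+" if rng.random() < 0.5 else "-"
        if orientation == "-":
            labels = (length - labels)[::-1]
        molecules.append(
            MoleculeMap(
                mol_id,
                float(length),
                [float(x) for x in labels],
                truth=MoleculeTruth(hap.haplotype, chrom, float(start), float(end),
                                    orientation, alpha),
            )
        )
    return molecules


def oracle_alignments(molecules: Sequence[MoleculeMap], refmap,
                      match_window: float = 500.0) -> list:
    """Perfect alignments derived from simulation truth (no search).

    Each label is undone through the recorded stretch factor and orientation,
    projected to genome coordinates, and matched to the nearest reference
    site within ``match_window``.  Useful as an idealized alignment set for
    separating alignment errors from calling errors.  Only meaningful when
    the molecules were simulated from the reference itself (no variants), or
    when positional drift from variants is below the match window.
    """
    from .core import AlignmentRecord

    out = []
    for mol in molecules:
        t = mol.truth
        if t is None:
            raise ValueError("oracle_alignments requires simulated molecules")
        sites = np.asarray(refmap[t.chromosome].sites)
        labels = np.asarray(mol.labels)
        if t.orientation == "-":
            labels = (mol.length - labels)[::-1]
        genome = t.start + labels / t.alpha
        j = np.clip(np.searchsorted(sites, genome), 1, len(sites) - 1)
        nearest = np.where(np.abs(sites[j] - genome) < np.abs(sites[j - 1] - genome),
                           j, j - 1)
        pairs = []
        used = set()
        for idx, (g, jj) in enumerate(zip(genome, nearest)):
            if abs(sites[jj] - g) <= match_window and jj not in used:
                used.add(jj)
                orig = idx if t.orientation == "+" else mol.n_labels - 1 - idx
                pairs.append((orig, int(jj)))
        if len(pairs) < 2:
            continue
        pairs.sort(key=lambda p: p[1])
        # cigar: M for matches, D for covered-but-unmatched sites, I for
        # unmatched labels between consecutive matches
        cigar = []
        fwd_idx = {p[1]: (p[0] if t.orientation == "+" else mol.n_labels - 1 - p[0])
                   for p in pairs}
        js = [p[1] for p in pairs]
        for (j1, j2) in zip(js, js[1:]):
            cigar.append("M")
            cigar.append("D" * (j2 - j1 - 1))
            cigar.append("I" * (abs(fwd_idx[j2] - fwd_idx[j1]) - 1))
        cigar.append("M")
        out.append(AlignmentRecord(
            molecule_id=mol.molecule_id,
            chromosome=t.chromosome,
            ref_start=float(t.start),
            ref_end=float(t.end),
            orientation=t.orientation,
            pairs=pairs,
            cigar="".join(cigar),
            confidence=100.0,
            source="oracle",
        ))
    return out


# ---------------------------------------------------------------------------
# Alignment-free distance-ratio datasets

@dataclass
class RatioLocus:
    """Observed-to-reference distance ratios at one reference interval."""

    chromosome: str
    left_site: float
    right_site: float
    d0: float
    ratios: np.ndarray
    truth_kind: str      # "none" | "insertion" | "deletion"
    truth_zygosity: str  # "hom" | "het" | "na"
    truth_size: float


def generate_ratio_dataset(
    truth: Sequence[TruthVariant],
    refmap,
    depth: float,
    params: ErrorModelParams,
    seed: int | np.random.Generator = 0,
    n_null_per_sv: float = 10.0,
) -> list[RatioLocus]:
    """Emit per-locus distance-ratio lists directly, bypassing alignment.

    Models the ideal situation with no alignment errors: per-locus support
    counts are Gaussian around the coverage depth (truncated at zero), each
    ratio is the true allele ratio times a Cauchy sizing factor, and for
    heterozygous loci each molecule comes from either allele with equal
    probability.  Null (non-SV) loci are included so the SV/non-SV locus mix
    follows the simulated genome.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    loci: list[RatioLocus] = []

    def draw_ratios(allele_ratios: list[float]) -> np.ndarray:
        m = max(0, int(round(rng.normal(depth, np.sqrt(depth)))))
        out = np.empty(m)
        for i in range(m):
            base = allele_ratios[int(rng.integers(len(allele_ratios)))]
            out[i] = base * _draw_alpha(rng, params.o_alpha, params.s_alpha)
        return np.sort(out)

    indels = [v for v in truth if v.kind in ("insertion", "deletion")]
    for v in indels:
        contig = refmap[v.chromosome]
        sites = np.asarray(contig.sites)
        mid = (v.start + v.end) / 2.0
        j = int(np.searchsorted(sites, mid))
        if j == 0 or j >= len(sites):
            continue
        left, right = sites[j - 1], sites[j]
        d0 = right - left
        sv_ratio = (d0 + v.size) / d0 if v.kind == "insertion" else max((d0 - v.size) / d0, 0.01)
        alleles = [sv_ratio] if v.zygosity == "hom" else [1.0, sv_ratio]
        loci.append(RatioLocus(v.chromosome, float(left), float(right), float(d0),
                               draw_ratios(alleles), v.kind, v.zygosity, v.size))

    n_null = int(round(n_null_per_sv * len(indels)))
    for contig in refmap:
        sites = np.asarray(contig.sites)
        if len(sites) < 2:
            continue
        for _ in range(n_null):
            j = int(rng.integers(1, len(sites)))
            left, right = sites[j - 1], sites[j]
            loci.append(RatioLocus(contig.name, float(left), float(right),
                                   float(right - left), draw_ratios([1.0]),
                                   "none", "na", 0.0))
        break  # null loci from the first contig are representative
    return loci


# ---------------------------------------------------------------------------
# Error-parameter estimation

def estimate_error_params(alignments, molecules, refmap) -> dict[str, float]:
    """Estimate (f_minus, f_plus, o_alpha, s_alpha) from aligned molecules.

    f_minus is the fraction of covered reference sites without a matched
    label (D ops among M+D); f_plus the rate of unmatched molecule labels per
    aligned reference bp (I ops); the stretch-factor location and scale come
    from the distance ratios of cleanly matched adjacent site pairs via the
    Cauchy quartile identities (median, IQR/2).
    """
    if not alignments:
        raise ValueError("no alignments to estimate from")
    mol_by_id = {m.molecule_id: m for m in molecules}
    n_match = n_del = n_ins = 0
    ref_bp = 0.0
    ratios: list[float] = []
    for rec in alignments:
        n_match += rec.cigar.count("M")
        n_del += rec.cigar.count("D")
        n_ins += rec.cigar.count("I")
        ref_bp += rec.ref_end - rec.ref_start
        mol = mol_by_id.get(rec.molecule_id)
        if mol is None:
            continue
        sites = refmap[rec.chromosome].sites
        labels = mol.labels
        for (i1, j1), (i2, j2) in zip(rec.pairs, rec.pairs[1:]):
            if j2 - j1 == 1 and abs(i2 - i1) == 1:  # clean adjacent pair
                d_ref = sites[j2] - sites[j1]
                d_mol = abs(labels[i2] - labels[i1])
                if d_ref > 0:
                    ratios.append(d_mol / d_ref)
    f_minus = n_del / (n_match + n_del) if (n_match + n_del) else 0.0
    f_plus = n_ins / ref_bp if ref_bp else 0.0
    if ratios:
        q1, med, q3 = np.percentile(ratios, [25, 50, 75])
        o_alpha, s_alpha = float(med), float((q3 - q1) / 2.0)
    else:
        o_alpha, s_alpha = 1.0, 0.0
    return {"f_minus": f_minus, "f_plus": f_plus, "o_alpha": o_alpha, "s_alpha": s_alpha}


# ---------------------------------------------------------------------------
# Truth-table IO (TSV, 1-based inclusive on disk)

_TRUTH_COLS = ["kind", "chromosome", "start", "end", "size", "zygosity",
               "haplotypes", "target", "copies"]


def write_truth_table(truth: Sequence[TruthVariant], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TRUTH_COLS) + "\n")
        for v in truth:
            fh.write("\t".join([
                v.kind, v.chromosome, str(int(v.start) + 1), str(int(v.end)),
                f"{v.size:.0f}", v.zygosity, ",".join(map(str, v.haplotypes)),
                f"{v.target:.0f}", str(v.copies),
            ]) + "\n")


def read_truth_table(path) -> list[TruthVariant]:
    out = []
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            out.append(TruthVariant(
                row["kind"], row["chromosome"], float(row["start"]) - 1.0,
                float(row["end"]), float(row["size"]), row["zygosity"],
                tuple(int(h) for h in row["haplotypes"].split(",") if h),
                target=float(row["target"]), copies=int(row["copies"]),
            ))
    return out
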