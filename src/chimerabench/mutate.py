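"""Genome mutation with complete ground truth.

Implements the simulation procedure the benchmark is built on: random point
substitutions (default rate 0.1%, one per 1,000 nucleotides), short indels
(default rate 0.01%, lengths uniform on [1, 15]), and reciprocal
translocations that exchange the 3' part of one gene with the 5' part of
another at annotated exon boundaries — exons are never split — producing two
fusion genes per event. Every change is recorded: a VCF-like record set for
point mutations, a fusion-truth table for translocations, and a liftover map
from reference to mutated coordinates so the annotation can be carried over.

The mutated genome is haploid; substituted bases are drawn uniformly among
the three alternatives.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .reference import GeneModel, ReferenceBundle, SizingError, write_gtf

_CODE_TO_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_TO_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_TO_CODE[_b] = _i


def seq_to_codes(seq: str) -> np.ndarray:
    arr = _BASE_TO_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValueError("sequence contains characters outside ACGT")
    return arr


def codes_to_seq(codes: np.ndarray) -> str:
    return _CODE_TO_BASE[codes].tobytes().decode("ascii")


@dataclass(frozen=True)
class MutationRates:
    """Per-nucleotide mutation rates.

    Defaults follow the simulator's stated regime: one substitution per
    1,000 nt and one indel per 10,000 nt, indel lengths uniform on [1, 15].
    """

    snv_rate: float = 0.001
    indel_rate: float = 0.0001
    indel_len_range: tuple[int, int] = (1, 15)

    def __post_init__(self) -> None:
        for r in (self.snv_rate, self.indel_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rate {r} outside [0, 1]")
        lo, hi = self.indel_len_range
        if not 1 <= lo <= hi:
            raise ValueError(f"bad indel_len_range {self.indel_len_range}")


@dataclass(frozen=True)
class MutationRecord:
    kind: str  # SNV | INS | DEL
    chrom: str
    position: int  # 0-based reference coordinate (first affected base; INS: base before)
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.kind == "SNV" and self.ref_allele == self.alt_allele:
            raise ValueError("SNV with alt == ref")
        if self.kind == "DEL" and len(self.ref_allele) < 1:
            raise ValueError("empty deletion")

    @property
    def length(self) -> int:
        if self.kind == "SNV":
            return 1
        return len(self.ref_allele) if self.kind == "DEL" else len(self.alt_allele)


@dataclass(frozen=True)
class FusionTruth:
    """One chimeric gene produced by a reciprocal translocation.

    Breakpoints are reference coordinates at annotated exon boundaries:
    ``breakpoint5`` is the half-open end of the last retained 5'-side exon,
    ``breakpoint3`` the start of the first retained 3'-side exon.
    """

    event_id: str
    gene5: str
    gene5_exons: tuple[int, int]  # retained exon index range [lo, hi) in the donor
    gene3: str
    gene3_exons: tuple[int, int]
    chrom5: str
    breakpoint5: int
    chrom3: str
    breakpoint3: int
    reciprocal_id: str
    junction_pos_mut: tuple[str, int] | None = None  # filled by apply_mutations


@dataclass
class MutatedGenome:
    sequences: dict[str, str]
    mutations: list[MutationRecord]
    fusions: list[FusionTruth]
    lifted_genes: list[GeneModel]
    # liftover: per reference chrom, mutated chrom index (-1 = deleted) and position
    _lift_chrom: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    _lift_pos: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    chrom_names: list[str] = field(default_factory=list)

    def lift(self, chrom: str, pos: int) -> tuple[str, int] | None:
        """Mutated coordinate of a reference base, or None if deleted."""
        ci = int(self._lift_chrom[chrom][pos])
        if ci < 0:
            return None
        return self.chrom_names[ci], int(self._lift_pos[chrom][pos])

    def lift_forward(self, chrom: str, pos: int, limit: int = 100) -> tuple[str, int] | None:
        """Lift, scanning forward past deleted bases (bounded scan)."""
        n = len(self._lift_chrom[chrom])
        for p in range(pos, min(pos + limit, n)):
            out = self.lift(chrom, p)
            if out is not None:
                return out
        return None


# ---------------------------------------------------------------------------
# Planning
# ---------------------------------------------------------------------------


def plan_point_mutations(
    reference: ReferenceBundle,
    rates: MutationRates,
    seed: int,
    protected_positions: dict[str, np.ndarray] | None = None,
) -> list[MutationRecord]:
    """Draw SNV and indel records independently per position.

    Each position is substituted with probability ``snv_rate`` (new base
    uniform over the three alternatives) and receives an indel with
    probability ``indel_rate`` (INS/DEL equiprobable, length uniform on the
    configured range, inserted bases uniform random). A position carries at
    most one record; colliding or out-of-bounds draws are re-drawn, and
    deletions never cross positions listed in ``protected_positions`` (used
    to keep planned translocation boundaries intact).
    """
    rng = np.random.default_rng(seed)
    records: list[MutationRecord] = []
    protected_positions = protected_positions or {}
    for chrom, seq in reference.sequences.items():
        codes = seq_to_codes(seq)
        n = len(codes)
        protected = np.asarray(sorted(protected_positions.get(chrom, [])), dtype=np.int64)

        snv_pos = np.nonzero(rng.random(n) < rates.snv_rate)[0]
        alt = (codes[snv_pos] + rng.integers(1, 4, size=snv_pos.size)) % 4
        occupied = set(snv_pos.tolist())
        for p, a in zip(snv_pos.tolist(), alt.tolist()):
            records.append(MutationRecord("SNV", chrom, p, codes_to_seq(codes[p : p + 1]),
                                          codes_to_seq(np.array([a], dtype=np.uint8))))

        indel_pos = np.nonzero(rng.random(n) < rates.indel_rate)[0]
        lo, hi = rates.indel_len_range
        for p in indel_pos.tolist():
            length = int(rng.integers(lo, hi + 1))
            is_ins = bool(rng.random() < 0.5)
            for _attempt in range(100):
                ok = p not in occupied and 0 < p < n
                if ok and not is_ins:
                    span_end = p + length
                    ok = span_end <= n
                    ok = ok and not any(q in occupied for q in range(p + 1, span_end))
                    if ok and protected.size:
                        j = np.searchsorted(protected, p)
                        ok = not (j < protected.size and protected[j] < span_end)
                if ok:
                    break
                p = int(rng.integers(1, n))
            else:  # pragma: no cover - pathological density
                continue
            if is_ins:
                ins = rng.integers(0, 4, size=length).astype(np.uint8)
                records.append(MutationRecord("INS", chrom, p, "", codes_to_seq(ins)))
                occupied.add(p)
            else:
                records.append(
                    MutationRecord("DEL", chrom, p, codes_to_seq(codes[p : p + length]), "")
                )
                occupied.update(range(p, p + length))
    return records


def plan_translocations(
    reference: ReferenceBundle, n_events: int, seed: int
) -> list[FusionTruth]:
    """Plan reciprocal translocations between pairs of multi-exon coding genes.

    Each event selects two distinct forward-strand coding genes, one internal
    exon boundary in each, and exchanges the 3' part of one gene with the 5'
    part of the other and the reciprocal — two fusion genes per event. A gene
    participates in at most one event; breakpoints always coincide with
    annotated exon boundaries.
    """
    rng = np.random.default_rng(seed)
    eligible = [g for g in reference.coding_genes() if g.strand == "+" and g.n_exons >= 2]
    if n_events == 0:
        return []
    if len(eligible) < 2 * n_events:
        raise SizingError(
            f"{n_events} translocations need {2 * n_events} eligible genes, have {len(eligible)}"
        )
    picks = rng.permutation(len(eligible))[: 2 * n_events]
    fusions: list[FusionTruth] = []
    for e in range(n_events):
        a = eligible[picks[2 * e]]
        b = eligible[picks[2 * e + 1]]
        # Internal boundary: retain >=1 exon on each side.
        i = int(rng.integers(1, a.n_exons))  # first 3'-side exon index in A
        j = int(rng.integers(1, b.n_exons))
        ev = f"T{e + 1:03d}"
        f1 = FusionTruth(
            event_id=f"{ev}a",
            gene5=a.gene_id, gene5_exons=(0, i),
            gene3=b.gene_id, gene3_exons=(j, b.n_exons),
            chrom5=a.chrom, breakpoint5=a.exons[i - 1][1],
            chrom3=b.chrom, breakpoint3=b.exons[j][0],
            reciprocal_id=f"{ev}b",
        )
        f2 = FusionTruth(
            event_id=f"{ev}b",
            gene5=b.gene_id, gene5_exons=(0, j),
            gene3=a.gene_id, gene3_exons=(i, a.n_exons),
            chrom5=b.chrom, breakpoint5=b.exons[j - 1][1],
            chrom3=a.chrom, breakpoint3=a.exons[i][0],
            reciprocal_id=f"{ev}a",
        )
        fusions.extend([f1, f2])
    return fusions


def fusion_protected_positions(fusions: list[FusionTruth]) -> dict[str, np.ndarray]:
    """Reference positions deletions must not cross (exon boundaries in use)."""
    out: dict[str, list[int]] = {}
    for f in fusions:
        out.setdefault(f.chrom5, []).append(f.breakpoint5 - 1)
        out.setdefault(f.chrom5, []).append(f.breakpoint5)
        out.setdefault(f.chrom3, []).append(f.breakpoint3)
    return {c: np.asarray(sorted(set(v)), dtype=np.int64) for c, v in out.items()}


# ---------------------------------------------------------------------------
# Application
# ---------------------------------------------------------------------------


def _swap_blocks(
    reference: ReferenceBundle, fusions: list[FusionTruth]
) -> dict[str, list[tuple[str, int, int]]]:
    """Per mutated chromosome, the ordered reference blocks composing it."""
    chrom_lens = {c: len(s) for c, s in reference.sequences.items()}
    # One replacement per fusion record: at the 5'-gene locus, the tail of the
    # 5' gene (from the first non-retained exon) is replaced by the partner's
    # exchanged 3' segment.
    replacements: dict[str, list[tuple[int, int, tuple[str, int, int]]]] = {
        c: [] for c in chrom_lens
    }
    for f in fusions:
        gene5 = reference.gene(f.gene5)
        # Tail removed from the 5' gene (its donated segment); the reciprocal
        # record contributes the mirror replacement, so the pair is a swap.
        tail_start = gene5.exons[f.gene5_exons[1]][0]
        tail_end = gene5.end
        incoming = (f.chrom3, f.breakpoint3, reference.gene(f.gene3).end)
        replacements[gene5.chrom].append((tail_start, tail_end, incoming))
    blocks: dict[str, list[tuple[str, int, int]]] = {}
    for chrom, n in chrom_lens.items():
        reps = sorted(replacements[chrom])
        out: list[tuple[str, int, int]] = []
        cursor = 0
        for start, end, incoming in reps:
            if start < cursor:
                raise ValueError("overlapping translocation segments")
            if start > cursor:
                out.append((chrom, cursor, start))
            out.append(incoming)
            cursor = end
        if cursor < n:
            out.append((chrom, cursor, n))
        blocks[chrom] = out
    return blocks


def apply_mutations(
    reference: ReferenceBundle,
    mutations: list[MutationRecord],
    fusions: list[FusionTruth],
) -> MutatedGenome:
    """Apply translocations, substitutions and indels; build truth and liftover.

    Translocations conserve total length; mutated length differs from the
    reference by the insertion/deletion balance. The liftover maps every
    retained reference base to its mutated coordinate, and the lifted
    annotation contains two fusion genes per translocation event in place of
    the two donor genes.
    """
    chrom_names = list(reference.sequences)
    ref_codes = {c: seq_to_codes(s) for c, s in reference.sequences.items()}
    for m in mutations:
        n = len(ref_codes[m.chrom])
        if not 0 <= m.position < n or (m.kind == "DEL" and m.position + m.length > n):
            raise ValueError(f"mutation at {m.chrom}:{m.position} out of bounds")

    # 1. substitutions change content only
    for m in mutations:
        if m.kind == "SNV":
            ref_codes[m.chrom][m.position] = _BASE_TO_CODE[ord(m.alt_allele)]

    # 2. translocation block assembly + preliminary liftover
    blocks = _swap_blocks(reference, fusions)
    prelim = {}
    lift_chrom = {c: np.full(len(s), -1, dtype=np.int16) for c, s in reference.sequences.items()}
    lift_pos = {c: np.full(len(s), -1, dtype=np.int64) for c, s in reference.sequences.items()}
    for ci, chrom in enumerate(chrom_names):
        pieces = []
        cursor = 0
        for src, s, e in blocks[chrom]:
            pieces.append(ref_codes[src][s:e])
            lift_chrom[src][s:e] = ci
            lift_pos[src][s:e] = cursor + np.arange(e - s, dtype=np.int64)
            cursor += e - s
        prelim[chrom] = np.concatenate(pieces) if pieces else np.empty(0, np.uint8)

    # 3. indels, per mutated chromosome, in mutated coordinates
    indels_by_chrom: dict[str, list[tuple[int, MutationRecord]]] = {c: [] for c in chrom_names}
    for m in mutations:
        if m.kind == "SNV":
            continue
        ci = int(lift_chrom[m.chrom][m.position])
        p = int(lift_pos[m.chrom][m.position])
        indels_by_chrom[chrom_names[ci]].append((p, m))

    mutated: dict[str, str] = {}
    for chrom in chrom_names:
        seq = prelim[chrom]
        events = sorted(indels_by_chrom[chrom], key=lambda t: t[0])
        pieces = []
        cursor = 0
        boundaries: list[int] = []
        shifts: list[int] = []
        del_spans: list[tuple[int, int]] = []
        total = 0
        for p, m in events:
            if m.kind == "DEL":
                pieces.append(seq[cursor:p])
                cursor = p + m.length
                del_spans.append((p, p + m.length))
                total -= m.length
                boundaries.append(p + m.length)
            else:  # INS after base p
                pieces.append(seq[cursor : p + 1])
                pieces.append(seq_to_codes(m.alt_allele))
                cursor = p + 1
                total += m.length
                boundaries.append(p + 1)
            shifts.append(total)
        pieces.append(seq[cursor:])
        mutated[chrom] = codes_to_seq(np.concatenate(pieces))

        # final liftover for all reference bases currently mapping to this chrom
        ci = chrom_names.index(chrom)
        if boundaries:
            b = np.asarray(boundaries)
            s = np.asarray([0] + shifts)
            for src in chrom_names:
                mask = lift_chrom[src] == ci
                if not mask.any():
                    continue
                pos = lift_pos[src][mask]
                shift = s[np.searchsorted(b, pos, side="right")]
                newpos = pos + shift
                lift_pos[src][mask] = newpos
                if del_spans:
                    ds = np.asarray([d[0] for d in del_spans])
                    de = np.asarray([d[1] for d in del_spans])
                    j = np.searchsorted(ds, pos, side="right") - 1
                    deleted = (j >= 0) & (pos < de[np.clip(j, 0, None)])
                    idx = np.nonzero(mask)[0][deleted]
                    lift_chrom[src][idx] = -1
                    lift_pos[src][idx] = -1

    mg = MutatedGenome(
        sequences=mutated,
        mutations=list(mutations),
        fusions=[],
        lifted_genes=[],
        _lift_chrom=lift_chrom,
        _lift_pos=lift_pos,
        chrom_names=chrom_names,
    )

    # 4. lifted annotation
    fused_gene_ids = {f.gene5 for f in fusions} | {f.gene3 for f in fusions}
    lifted: list[GeneModel] = []
    for g in reference.genes:
        if g.gene_id in fused_gene_ids:
            continue
        new_exons = []
        new_chrom = None
        for s, e in g.exons:
            a = mg.lift_forward(g.chrom, s)
            bmap = mg.lift_forward(g.chrom, e - 1)
            if a is None or bmap is None or a[0] != bmap[0] or bmap[1] < a[1]:
                continue
            new_chrom = a[0]
            new_exons.append((a[1], bmap[1] + 1))
        if new_exons:
            lifted.append(
                GeneModel(g.gene_id, new_chrom, g.strand, tuple(new_exons), g.biotype, g.parent_id)
            )

    out_fusions: list[FusionTruth] = []
    for f in fusions:
        g5 = reference.gene(f.gene5)
        g3 = reference.gene(f.gene3)
        exon_refs = [ (g5.chrom, s, e) for s, e in g5.exons[f.gene5_exons[0] : f.gene5_exons[1]] ]
        exon_refs += [ (g3.chrom, s, e) for s, e in g3.exons[f.gene3_exons[0] : f.gene3_exons[1]] ]
        new_exons = []
        for chrom, s, e in exon_refs:
            a = mg.lift_forward(chrom, s)
            bmap = mg.lift_forward(chrom, e - 1)
            if a is None or bmap is None:
                raise ValueError(f"fusion exon lost during liftover for {f.event_id}")
            new_exons.append((a[1], bmap[1] + 1))
        mchrom = mg.lift_forward(f.chrom5, g5.exons[0][0])[0]
        lifted.append(GeneModel(f"FUS_{f.event_id}", mchrom, "+", tuple(new_exons), "fusion"))
        jpos = mg.lift_forward(f.chrom3, f.breakpoint3)
        out_fusions.append(
            dataclasses.replace(f, junction_pos_mut=(jpos[0], int(jpos[1])))
        )

    lifted.sort(key=lambda g: (g.chrom, g.start))
    mg.lifted_genes = lifted
    mg.fusions = out_fusions
    return mg


def mutate_genome(
    reference: ReferenceBundle,
    rates: MutationRates,
    n_translocations: int,
    seed: int,
) -> MutatedGenome:
    """Plan and apply a full mutation round (convenience wrapper)."""
    fusions = plan_translocations(reference, n_translocations, seed)
    muts = plan_point_mutations(
        reference, rates, seed + 1, protected_positions=fusion_protected_positions(fusions)
    )
    return apply_mutations(reference, muts, fusions)


# ---------------------------------------------------------------------------
# Truth files
# ---------------------------------------------------------------------------


def write_truth(mutated: MutatedGenome, reference: ReferenceBundle, out_dir: str | Path) -> None:
    """Write VCF (point mutations), fusion TSV + BED6, and lifted GTF."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_vcf(mutated.mutations, reference, out / "mutations.vcf")
    fusions_to_frame(mutated.fusions).to_csv(out / "fusions.tsv", sep="\t", index=False)
    with open(out / "fusions.bed", "w") as fh:
        for f in mutated.fusions:
            fh.write(f"{f.chrom5}\t{f.breakpoint5 - 1}\t{f.breakpoint5}\t{f.event_id}_5p\t0\t+\n")
            fh.write(f"{f.chrom3}\t{f.breakpoint3}\t{f.breakpoint3 + 1}\t{f.event_id}_3p\t0\t+\n")
    write_gtf(mutated.lifted_genes, out / "lifted.gtf")


def fusions_to_frame(fusions: list[FusionTruth]) -> pd.DataFrame:
    rows = []
    for f in fusions:
        rows.append(
            {
                "event_id": f.event_id,
                "gene5": f.gene5,
                "gene5_exon_lo": f.gene5_exons[0],
                "gene5_exon_hi": f.gene5_exons[1],
                "gene3": f.gene3,
                "gene3_exon_lo": f.gene3_exons[0],
                "gene3_exon_hi": f.gene3_exons[1],
                "chrom5": f.chrom5,
                "breakpoint5": f.breakpoint5,
                "chrom3": f.chrom3,
                "breakpoint3": f.breakpoint3,
                "reciprocal_id": f.reciprocal_id,
                "junction_chrom_mut": f.junction_pos_mut[0] if f.junction_pos_mut else ".",
                "junction_pos_mut": f.junction_pos_mut[1] if f.junction_pos_mut else -1,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "event_id", "gene5", "gene5_exon_lo", "gene5_exon_hi", "gene3",
            "gene3_exon_lo", "gene3_exon_hi", "chrom5", "breakpoint5", "chrom3",
            "breakpoint3", "reciprocal_id", "junction_chrom_mut", "junction_pos_mut",
        ],
    )


def read_fusion_tsv(path: str | Path) -> list[FusionTruth]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, r in df.iterrows():
        out.append(
            FusionTruth(
                event_id=r.event_id,
                gene5=r.gene5, gene5_exons=(int(r.gene5_exon_lo), int(r.gene5_exon_hi)),
                gene3=r.gene3, gene3_exons=(int(r.gene3_exon_lo), int(r.gene3_exon_hi)),
                chrom5=r.chrom5, breakpoint5=int(r.breakpoint5),
                chrom3=r.chrom3, breakpoint3=int(r.breakpoint3),
                reciprocal_id=r.reciprocal_id,
                junction_pos_mut=None
                if r.junction_pos_mut < 0
                else (r.junction_chrom_mut, int(r.junction_pos_mut)),
            )
        )
    return out


def _write_vcf(mutations: list[MutationRecord], reference: ReferenceBundle, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, seq in reference.sequences.items():
            fh.write(f"##contig=<ID={chrom},length={len(seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        order = {c: i for i, c in enumerate(reference.sequences)}
        for m in sorted(mutations, key=lambda m: (order[m.chrom], m.position)):
            seq = reference.sequences[m.chrom]
            if m.kind == "SNV":
                pos, ref, alt = m.position + 1, m.ref_allele, m.alt_allele
            elif m.kind == "INS":
                anchor = seq[m.position]
                pos, ref, alt = m.position + 1, anchor, anchor + m.alt_allele
            else:  # DEL anchored at the preceding base
                anchor = seq[m.position - 1]
                pos, ref, alt = m.position, anchor + m.ref_allele, anchor
            fh.write(f"{m.chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\tTYPE={m.kind}\n")


def read_vcf(path: str | Path) -> list[MutationRecord]:
    """Read back the truth VCF written by :func:`write_truth` (via pysam)."""
    import pysam

    out: list[MutationRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            kind = rec.info["TYPE"]
            if isinstance(kind, tuple):
                kind = kind[0]
            alt = rec.alts[0]
            if kind == "SNV":
                out.append(MutationRecord("SNV", rec.chrom, rec.pos - 1, rec.ref, alt))
            elif kind == "INS":
                out.append(MutationRecord("INS", rec.chrom, rec.pos - 1, "", alt[1:]))
            else:
                out.append(MutationRecord("DEL", rec.chrom, rec.pos, rec.ref[1:], ""))
    return out
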