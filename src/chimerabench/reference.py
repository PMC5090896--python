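"""Synthetic reference genomes with multi-exon gene annotation.

The downstream stages (mutator, read simulator, break profiler) need a
reference with the structural ingredients of a real annotated genome:
multi-exon genes separated by intergenic space, exact repeat copies that
create mapping ambiguity, and intronless pseudogene copies of coding genes.
This module builds such a reference deterministically from a seed, and
round-trips it through FASTA + GTF so the pipeline can also run on
user-supplied files.

Coordinates are 0-based half-open in memory and 1-based inclusive in GTF.
"""

from __future__ import annotations


from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_CODE_TO_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)


class SizingError(ValueError):
    """Requested elements do not fit on the chromosomes."""


@dataclass(frozen=True)
class GeneModel:
    """A gene with one transcript: an ordered chain of disjoint exons."""

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    biotype: str = "coding"
    parent_id: str | None = None  # pseudogenes record the copied gene

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        prev_end = -1
        for start, end in self.exons:
            if end <= start:
                raise ValueError(f"gene {self.gene_id}: empty exon ({start},{end})")
            if start < prev_end:
                raise ValueError(f"gene {self.gene_id}: exons overlap or unsorted")
            prev_end = end

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)


@dataclass(frozen=True)
class RepeatCopy:
    """An exact duplication: [start, end) on chrom copies src_chrom[src_start: ...]."""

    chrom: str
    start: int
    end: int
    src_chrom: str
    src_start: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ReferenceBundle:
    """Genome sequences plus gene models plus flagged repeat intervals."""

    sequences: dict[str, str]
    genes: list[GeneModel]
    repeats: list[RepeatCopy] = field(default_factory=list)

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def coding_genes(self) -> list[GeneModel]:
        return [g for g in self.genes if g.biotype == "coding"]

    def validate(self) -> None:
        for g in self.genes:
            if g.chrom not in self.sequences:
                raise ValueError(f"gene {g.gene_id} on unknown chrom {g.chrom}")
            if g.end > len(self.sequences[g.chrom]):
                raise ValueError(f"gene {g.gene_id} exceeds chromosome length")
        for r in self.repeats:
            dest = self.sequences[r.chrom][r.start : r.end]
            src = self.sequences[r.src_chrom][r.src_start : r.src_start + r.length]
            if dest != src:
                raise ValueError(f"repeat at {r.chrom}:{r.start} diverges from its source")


@dataclass(frozen=True)
class ReferenceSpec:
    """Sizing knobs for the synthetic reference.

    Defaults are desk scale: two 1 Mb chromosomes, 150 one-transcript genes.
    ``repeat_fraction`` of the genome is covered by exact copies of segments
    sampled inside coding genes, so transcript reads can hit ambiguous
    sequence; ``pseudogene_fraction`` of the genes are intronless copies of a
    coding gene placed elsewhere.
    """

    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_genes: int = 150
    exons_per_gene_range: tuple[int, int] = (3, 8)
    exon_len_range: tuple[int, int] = (80, 400)
    intron_len_range: tuple[int, int] = (200, 2000)
    repeat_fraction: float = 0.04
    repeat_len_range: tuple[int, int] = (400, 1200)
    pseudogene_fraction: float = 0.06
    min_gap: int = 200
    minus_strand_fraction: float = 0.5


def _plan_coding_gene(spec: ReferenceSpec, rng: np.random.Generator) -> tuple[tuple[int, int], ...]:
    """Exon chain in gene-local coordinates starting at 0."""
    n_ex = int(rng.integers(spec.exons_per_gene_range[0], spec.exons_per_gene_range[1] + 1))
    exon_lens = rng.integers(spec.exon_len_range[0], spec.exon_len_range[1] + 1, size=n_ex)
    intron_lens = rng.integers(spec.intron_len_range[0], spec.intron_len_range[1] + 1, size=n_ex - 1)
    exons = []
    pos = 0
    for i, el in enumerate(exon_lens):
        exons.append((pos, pos + int(el)))
        pos += int(el)
        if i < n_ex - 1:
            pos += int(intron_lens[i])
    return tuple(exons)


def build_reference(spec: ReferenceSpec, seed: int) -> ReferenceBundle:
    """Build a synthetic annotated genome, deterministically for a fixed seed.

    Raises :class:`SizingError` when the requested genes/repeats cannot be
    placed without overlap.
    """
    rng = np.random.default_rng(seed)
    chrom_names = [f"chr{i + 1}" for i in range(spec.n_chroms)]

    n_pseudo = int(round(spec.pseudogene_fraction * spec.n_genes))
    n_coding = spec.n_genes - n_pseudo
    if n_coding < 1:
        raise SizingError("pseudogene_fraction leaves no coding genes")

    coding_plans = [_plan_coding_gene(spec, rng) for _ in range(n_coding)]
    pseudo_parents = rng.integers(0, n_coding, size=n_pseudo)

    # Repeat destination slots; sources are chosen after layout.
    repeat_lens: list[int] = []
    target = spec.repeat_fraction * spec.n_chroms * spec.chrom_length
    while sum(repeat_lens) < target:
        repeat_lens.append(int(rng.integers(spec.repeat_len_range[0], spec.repeat_len_range[1] + 1)))
    if spec.repeat_fraction == 0:
        repeat_lens = []

    # Elements to place: ("coding", idx, span) / ("pseudo", idx, span) / ("repeat", idx, span)
    elements: list[tuple[str, int, int]] = []
    for i, plan in enumerate(coding_plans):
        elements.append(("coding", i, plan[-1][1]))
    for i, parent in enumerate(pseudo_parents):
        span = sum(e - s for s, e in coding_plans[parent])
        elements.append(("pseudo", i, span))
    for i, ln in enumerate(repeat_lens):
        elements.append(("repeat", i, ln))
    order = rng.permutation(len(elements))
    elements = [elements[i] for i in order]

    # Greedy balance across chromosomes, then random-gap layout per chromosome.
    per_chrom: list[list[tuple[str, int, int]]] = [[] for _ in chrom_names]
    fill = np.zeros(spec.n_chroms)
    for el in elements:
        c = int(np.argmin(fill))
        per_chrom[c].append(el)
        fill[c] += el[2] + spec.min_gap

    placements: dict[tuple[str, int], tuple[int, int]] = {}  # (kind, idx) -> (chrom_i, start)
    for ci, els in enumerate(per_chrom):
        total = sum(e[2] for e in els)
        n = len(els)
        slack = spec.chrom_length - total - spec.min_gap * (n + 1)
        if slack < 0:
            raise SizingError(
                f"{chrom_names[ci]}: need {total + spec.min_gap * (n + 1)} bases "
                f"for {n} elements but chrom_length is {spec.chrom_length}"
            )
        parts = rng.multinomial(slack, np.full(n + 1, 1.0 / (n + 1))) if n else [slack]
        pos = 0
        for j, (kind, idx, span) in enumerate(els):
            pos += spec.min_gap + int(parts[j])
            placements[(kind, idx)] = (ci, pos)
            pos += span

    # Sequence: i.i.d. uniform bases, then pseudogene and repeat copies.
    seqs = [rng.integers(0, 4, size=spec.chrom_length, dtype=np.uint8) for _ in chrom_names]

    genes: list[GeneModel] = []
    for i, plan in enumerate(coding_plans):
        ci, start = placements[("coding", i)]
        strand = "-" if rng.random() < spec.minus_strand_fraction else "+"
        exons = tuple((start + s, start + e) for s, e in plan)
        genes.append(GeneModel(f"G{i + 1:04d}", chrom_names[ci], strand, exons, "coding"))

    for i, parent in enumerate(pseudo_parents):
        ci, start = placements[("pseudo", i)]
        pg = genes[parent]
        # Intronless copy of the parent's spliced (genomic-order) exon sequence.
        pci = chrom_names.index(pg.chrom)
        chunks = [seqs[pci][s:e] for s, e in pg.exons]
        body = np.concatenate(chunks)
        seqs[ci][start : start + len(body)] = body
        genes.append(
            GeneModel(
                f"PG{i + 1:03d}",
                chrom_names[ci],
                "+",
                ((start, start + len(body)),),
                "pseudogene",
                parent_id=pg.gene_id,
            )
        )

    repeats: list[RepeatCopy] = []
    coding = [g for g in genes if g.biotype == "coding"]
    for i, ln in enumerate(repeat_lens):
        ci, start = placements[("repeat", i)]
        # Source: a window inside a coding gene so transcript reads see the copy.
        src_gene = coding[int(rng.integers(0, len(coding)))]
        span = src_gene.end - src_gene.start
        ln_eff = min(ln, span)
        off = int(rng.integers(0, span - ln_eff + 1))
        src_ci = chrom_names.index(src_gene.chrom)
        src_start = src_gene.start + off
        seqs[ci][start : start + ln_eff] = seqs[src_ci][src_start : src_start + ln_eff]
        repeats.append(RepeatCopy(chrom_names[ci], start, start + ln_eff, src_gene.chrom, src_start))

    sequences = {
        name: _CODE_TO_BASE[arr].tobytes().decode("ascii") for name, arr in zip(chrom_names, seqs)
    }
    genes.sort(key=lambda g: (g.chrom, g.start))
    bundle = ReferenceBundle(sequences=sequences, genes=genes, repeats=repeats)
    bundle.validate()
    return bundle


def random_genome(lengths: dict[str, int], seed: int) -> ReferenceBundle:
    """Annotation-free random genome (uniform bases), e.g. for rate studies."""
    rng = np.random.default_rng(seed)
    sequences = {
        name: _CODE_TO_BASE[rng.integers(0, 4, size=n, dtype=np.uint8)]
        .tobytes()
        .decode("ascii")
        for name, n in lengths.items()
    }
    return ReferenceBundle(sequences=sequences, genes=[], repeats=[])


# ---------------------------------------------------------------------------
# FASTA + GTF round trip
# ---------------------------------------------------------------------------


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def _gtf_attrs(pairs: list[tuple[str, str]]) -> str:
    return " ".join(f'{k} "{v}";' for k, v in pairs)


def write_gtf(bundle_or_genes, path: str | Path) -> None:
    """Write gene/exon (and repeat_region) features, 1-based inclusive."""
    if isinstance(bundle_or_genes, ReferenceBundle):
        genes = bundle_or_genes.genes
        repeats = bundle_or_genes.repeats
    else:
        genes, repeats = list(bundle_or_genes), []
    with open(path, "w") as fh:
        fh.write("##gff-version 2\n")
        for g in genes:
            attrs = [("gene_id", g.gene_id), ("transcript_id", f"{g.gene_id}.t1"),
                     ("gene_biotype", g.biotype)]
            if g.parent_id:
                attrs.append(("parent_gene_id", g.parent_id))
            base = f"{g.chrom}\tchimerabench\t%s\t%d\t%d\t.\t{g.strand}\t.\t{_gtf_attrs(attrs)}\n"
            fh.write(base % ("gene", g.start + 1, g.end))
            for s, e in g.exons:
                fh.write(base % ("exon", s + 1, e))
        for i, r in enumerate(repeats):
            attrs = [("repeat_id", f"R{i + 1:03d}"), ("src_chrom", r.src_chrom),
                     ("src_start", str(r.src_start + 1))]
            fh.write(
                f"{r.chrom}\tchimerabench\trepeat_region\t{r.start + 1}\t{r.end}\t.\t+\t.\t"
                f"{_gtf_attrs(attrs)}\n"
            )


def _parse_attrs(s: str) -> dict[str, str]:
    out = {}
    for part in s.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, val = part.partition(" ")
        out[key] = val.strip().strip('"')
    return out


def read_gtf(path: str | Path) -> tuple[list[GeneModel], list[RepeatCopy]]:
    """Parse the GTF dialect written by :func:`write_gtf` (tolerant of extras)."""
    exons: dict[str, dict] = {}
    repeats: list[RepeatCopy] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(f"malformed GTF line {lineno}: expected 9 fields, got {len(fields)}")
            chrom, _src, feature, start_s, end_s, _score, strand, _frame, attr_s = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"malformed GTF line {lineno}: non-integer coordinates") from exc
            if end < start:
                raise ValueError(f"malformed GTF line {lineno}: end {end} < start {start}")
            attrs = _parse_attrs(attr_s)
            if feature == "exon":
                gid = attrs.get("gene_id")
                if gid is None:
                    raise ValueError(f"malformed GTF line {lineno}: exon without gene_id")
                rec = exons.setdefault(
                    gid,
                    {"chrom": chrom, "strand": strand,
                     "biotype": attrs.get("gene_biotype", "coding"),
                     "parent": attrs.get("parent_gene_id"), "exons": []},
                )
                rec["exons"].append((start - 1, end))
            elif feature == "repeat_region":
                repeats.append(
                    RepeatCopy(chrom, start - 1, end, attrs["src_chrom"], int(attrs["src_start"]) - 1)
                )
    genes = [
        GeneModel(
            gid,
            rec["chrom"],
            rec["strand"],
            tuple(sorted(rec["exons"])),
            rec["biotype"],
            parent_id=rec["parent"],
        )
        for gid, rec in exons.items()
    ]
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes, repeats


def write_reference(bundle: ReferenceBundle, fasta_path: str | Path, gtf_path: str | Path) -> None:
    write_fasta(bundle.sequences, fasta_path)
    write_gtf(bundle, gtf_path)


def read_reference(fasta_path: str | Path, gtf_path: str | Path) -> ReferenceBundle:
    sequences = read_fasta(fasta_path)
    genes, repeats = read_gtf(gtf_path)
    bundle = ReferenceBundle(sequences=sequences, genes=genes, repeats=repeats)
    bundle.validate()
    return bundle
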