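"""Truth-preserving paired-end RNA-seq simulation.

Expression follows a power law over expressed transcripts (fusion
transcripts compete in the same pool and are therefore not necessarily
expressed nor covered). Fragments are drawn from a truncated normal,
mates are read_length bases from either fragment end (mate 2
reverse-complemented), and sequencing noise is a uniform per-base
substitution error. Every read pair carries its ground truth in the read
name and in a sidecar TSV: reads spanning a fusion junction by at least
``min_overhang`` bases on both sides are labelled chimeric with the
junction offset inside each mate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .mutate import MutatedGenome
from .reference import GeneModel

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ExpressionProfile:
    """Expected read-pair counts per transcript (sums to the library size)."""

    expected: dict[str, float]
    zipf_exponent: float
    expressed_fraction: float

    @property
    def library_size(self) -> float:
        return float(sum(self.expected.values()))


@dataclass(frozen=True)
class ReadRecord:
    read_id: str
    mate1_seq: str
    mate2_seq: str
    transcript_id: str
    start: int  # fragment start on the transcript
    fragment: int
    label: str  # chimeric_true | normal
    event_id: str | None
    junction_offset1: int  # junction position within mate1, -1 if absent
    junction_offset2: int  # junction position within mate2 (mate orientation), -1 if absent

    @property
    def name(self) -> str:
        ev = self.event_id or "."
        lab = "1" if self.label == "chimeric_true" else "0"
        return f"{self.read_id}|{lab}|{ev}|{self.junction_offset1}|{self.junction_offset2}"


def parse_read_name(name: str) -> dict:
    """Invert :attr:`ReadRecord.name` (truth carried in FASTQ headers)."""
    rid, lab, ev, o1, o2 = name.split("|")
    return {
        "read_id": rid,
        "label": "chimeric_true" if lab == "1" else "normal",
        "event_id": None if ev == "." else ev,
        "junction_offset1": int(o1),
        "junction_offset2": int(o2),
    }


def transcript_sequences(mutated: MutatedGenome) -> dict[str, str]:
    """Spliced transcript per lifted gene (strand-aware; one per gene).

    Pseudogenes are excluded: the simulation does not model transcribed
    pseudogenes, they act purely as mapping decoys.
    """
    out: dict[str, str] = {}
    for g in mutated.lifted_genes:
        if g.biotype == "pseudogene":
            continue
        seq = "".join(mutated.sequences[g.chrom][s:e] for s, e in g.exons)
        if g.strand == "-":
            seq = revcomp(seq)
        out[g.gene_id] = seq
    return out


def fusion_junction_positions(mutated: MutatedGenome) -> dict[str, tuple[str, int]]:
    """transcript_id -> (event_id, junction offset in the spliced transcript)."""
    genes = {g.gene_id: g for g in mutated.lifted_genes}
    out = {}
    for f in mutated.fusions:
        gid = f"FUS_{f.event_id}"
        g = genes[gid]
        n5 = f.gene5_exons[1] - f.gene5_exons[0]
        jpos = sum(e - s for s, e in g.exons[:n5])
        out[gid] = (f.event_id, jpos)
    return out


def assign_expression(
    lifted_genes: list[GeneModel],
    library_size: int,
    zipf_exponent: float = 0.6,
    expressed_fraction: float = 0.85,
    seed: int = 0,
) -> ExpressionProfile:
    """Power-law expected counts over a random expressed subset of transcripts.

    Expressed transcripts get expected counts proportional to
    rank^(-zipf_exponent); the rest (possibly including fusion transcripts)
    get zero. The expected counts sum exactly to ``library_size``.
    """
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    rng = np.random.default_rng(seed)
    ids = sorted(g.gene_id for g in lifted_genes if g.biotype != "pseudogene")
    n_expr = max(1, int(round(expressed_fraction * len(ids))))
    chosen = rng.permutation(len(ids))[:n_expr]
    weights = (np.arange(n_expr, dtype=float) + 1.0) ** (-zipf_exponent)
    weights *= library_size / weights.sum()
    expected = {tid: 0.0 for tid in ids}
    for rank, idx in enumerate(chosen):
        expected[ids[idx]] = float(weights[rank])
    return ExpressionProfile(expected, zipf_exponent, expressed_fraction)


def simulate_reads(
    mutated: MutatedGenome,
    profile: ExpressionProfile,
    n_pairs: int,
    read_length: int = 100,
    fragment_mean: float = 250.0,
    fragment_sd: float = 50.0,
    base_error_rate: float = 0.002,
    seed: int = 0,
    min_overhang: int = 1,
) -> list[ReadRecord]:
    """Simulate ``n_pairs`` read pairs from the spliced transcriptome."""
    if fragment_mean < read_length:
        raise ValueError("fragment_mean must be >= read_length")
    rng = np.random.default_rng(seed)
    seqs = transcript_sequences(mutated)
    junctions = fusion_junction_positions(mutated)

    usable: list[str] = []
    for tid in sorted(seqs):
        if len(seqs[tid]) < read_length:
            if profile.expected.get(tid, 0.0) > 0:
                warnings.warn(f"transcript {tid} shorter than read_length; skipped")
            continue
        usable.append(tid)
    p = np.array([profile.expected.get(tid, 0.0) for tid in usable], dtype=float)
    if p.sum() <= 0:
        raise ValueError("no expressed transcript is long enough to sequence")
    counts = rng.multinomial(n_pairs, p / p.sum())

    records: list[ReadRecord] = []
    idx = 0
    for tid, cnt in zip(usable, counts):
        if cnt == 0:
            continue
        t = seqs[tid]
        L = len(t)
        frags = rng.normal(fragment_mean, fragment_sd, size=cnt)
        frags = np.clip(np.rint(frags), read_length, L).astype(np.int64)
        starts = rng.integers(0, L - frags + 1)
        n_err = rng.binomial(read_length, base_error_rate, size=(cnt, 2))
        ev, jpos = junctions.get(tid, (None, None))
        for s, fr, ne1, ne2 in zip(starts.tolist(), frags.tolist(), n_err[:, 0], n_err[:, 1]):
            m1 = t[s : s + read_length]
            m2 = revcomp(t[s + fr - read_length : s + fr])
            if ne1:
                m1 = _add_errors(m1, int(ne1), rng)
            if ne2:
                m2 = _add_errors(m2, int(ne2), rng)
            o1 = o2 = -1
            if jpos is not None:
                if min_overhang <= jpos - s <= read_length - min_overhang:
                    o1 = jpos - s
                fend = s + fr
                if min_overhang <= fend - jpos <= read_length - min_overhang:
                    o2 = fend - jpos
            label = "chimeric_true" if (o1 >= 0 or o2 >= 0) else "normal"
            records.append(
                ReadRecord(
                    read_id=f"r{idx}",
                    mate1_seq=m1,
                    mate2_seq=m2,
                    transcript_id=tid,
                    start=s,
                    fragment=fr,
                    label=label,
                    event_id=ev if label == "chimeric_true" else None,
                    junction_offset1=o1,
                    junction_offset2=o2,
                )
            )
            idx += 1
    return records


def _add_errors(seq: str, n: int, rng: np.random.Generator) -> str:
    arr = list(seq)
    pos = rng.choice(len(arr), size=min(n, len(arr)), replace=False)
    for p in pos:
        alts = [b for b in "ACGT" if b != arr[p]]
        arr[p] = alts[int(rng.integers(0, 3))]
    return "".join(arr)


# ---------------------------------------------------------------------------
# FASTQ + truth TSV
# ---------------------------------------------------------------------------


def write_fastq(records: list[ReadRecord], prefix: str | Path) -> tuple[Path, Path]:
    """Write mates to <prefix>_1.fastq / <prefix>_2.fastq (quality constant I)."""
    prefix = Path(prefix)
    p1, p2 = Path(f"{prefix}_1.fastq"), Path(f"{prefix}_2.fastq")
    with open(p1, "w") as f1, open(p2, "w") as f2:
        for r in records:
            q1 = "I" * len(r.mate1_seq)
            q2 = "I" * len(r.mate2_seq)
            f1.write(f"@{r.name}\n{r.mate1_seq}\n+\n{q1}\n")
            f2.write(f"@{r.name}\n{r.mate2_seq}\n+\n{q2}\n")
    return p1, p2


def truth_frame(records: list[ReadRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "read_id": [r.read_id for r in records],
            "transcript_id": [r.transcript_id for r in records],
            "start": [r.start for r in records],
            "fragment": [r.fragment for r in records],
            "label": [r.label for r in records],
            "event_id": [r.event_id or "." for r in records],
            "junction_offset1": [r.junction_offset1 for r in records],
            "junction_offset2": [r.junction_offset2 for r in records],
        }
    )


def read_fastq_pairs(p1: str | Path, p2: str | Path) -> list[tuple[str, str, str]]:
    """(name, mate1, mate2) triples from a FASTQ pair written by write_fastq."""
    from Bio import SeqIO

    it1 = SeqIO.parse(str(p1), "fastq")
    it2 = SeqIO.parse(str(p2), "fastq")
    out = []
    for r1, r2 in zip(it1, it2):
        if r1.id != r2.id:
            raise ValueError(f"unsynchronised FASTQ pair at {r1.id} / {r2.id}")
        out.append((r1.id, str(r1.seq), str(r2.seq)))
    return out
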