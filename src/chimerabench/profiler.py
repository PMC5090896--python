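"""Break detection and read-level features for candidate chimeric junctions.

For every read we build two profiles over its k-mers: the *location
profile* (all exact-match genomic locations of each k-mer, both strands)
and the *support profile* (each k-mer's occurrence count over the whole
read collection). A *break* is a maximal run of location-less k-mers —
an error-free junction between two genomic loci produces a run of exactly
k-1 of them. Candidate junctions are called from the anchors flanking a
break and classified as splice (colinear, intron-sized gap), chimera
candidate (discordant chromosome, order or strand, or beyond the
read-through distance) or unresolved. Eight quantitative features
summarise each candidate's break for the classifiers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kmer import GenomeKmerIndex, SupportTable, encode_bases, kmer_codes, kmer_codes_2d
from .mutate import FusionTruth
from .reads import ReadRecord
from .reference import RepeatCopy

FEATURES8 = [
    "score_break_length",
    "score_nb_merge",
    "score_break_variance",
    "score_is_duplicate",
    "score_has_repeat",
    "coefficient_variation",
    "mean_amplitude",
    "coefficient_dispersion_interquartile",
]
# The most discriminative subset used by default for modelling
# (score_has_repeat in particular carries no signal and is excluded).
TOP3 = ["score_is_duplicate", "coefficient_variation", "score_break_length"]


@dataclass(frozen=True)
class ProfilerParams:
    k: int = 22
    max_locations: int = 16
    merge_gap: int = 2
    intron_min: int = 50
    intron_max: int = 300_000
    readthrough_max: int = 1_000_000
    tolerance: int = 5


@dataclass(frozen=True)
class Break:
    start: int  # inclusive k-mer index of the first location-less position
    end: int  # inclusive k-mer index of the last
    n_merged: int = 1  # number of elementary runs merged into this break

    @property
    def width(self) -> int:
        return self.end - self.start + 1


@dataclass
class KmerProfile:
    read_id: str
    seq: str
    codes: np.ndarray
    mult: np.ndarray  # genomic locations per k-mer (both strands)
    support: np.ndarray  # read-collection occurrence count per k-mer

    @property
    def mapped(self) -> np.ndarray:
        return self.mult > 0

    def __len__(self) -> int:
        return len(self.codes)


@dataclass
class CandidateJunction:
    read_id: str
    brk: Break
    left_anchor: tuple[str, int, str] | None  # (chrom, kmer start, strand)
    right_anchor: tuple[str, int, str] | None
    chrom_l: str = ""
    pos_l: int = -1
    strand_l: str = ""
    chrom_r: str = ""
    pos_r: int = -1
    strand_r: str = ""
    category: str = "unresolved"  # chimera_candidate | splice | unresolved
    class_hint: int = 0  # Gingeras class hint for discordant candidates
    left_mult: int = 0
    right_mult: int = 0


def profile_read(
    read_seq: str, index: GenomeKmerIndex, support: SupportTable, read_id: str = "read"
) -> KmerProfile | None:
    """Location/support profile of one read; None (with warning) if too short."""
    k = index.k
    if len(read_seq) < k:
        warnings.warn(f"read {read_id} shorter than k={k}; skipped")
        return None
    codes = kmer_codes(encode_bases(read_seq), k)
    return KmerProfile(
        read_id=read_id,
        seq=read_seq,
        codes=codes,
        mult=index.multiplicity(codes),
        support=support.counts(codes),
    )


def detect_breaks(mapped: np.ndarray | list, merge_gap: int = 2) -> list[Break]:
    """Maximal runs of location-less k-mers, merging runs separated by at
    most ``merge_gap`` mapped positions."""
    m = np.asarray(mapped, dtype=bool)
    if m.size == 0 or m.all():
        return []
    padded = np.concatenate(([True], m, [True]))
    d = np.diff(padded.astype(np.int8))
    starts = np.nonzero(d == -1)[0]
    ends = np.nonzero(d == 1)[0] - 1
    breaks: list[Break] = []
    for s, e in zip(starts.tolist(), ends.tolist()):
        if breaks and s - breaks[-1].end - 1 <= merge_gap:
            prev = breaks[-1]
            breaks[-1] = Break(prev.start, e, prev.n_merged + 1)
        else:
            breaks.append(Break(s, e, 1))
    return breaks


def _junction_coords(
    anchor: tuple[str, int, str], k: int, side: str
) -> tuple[str, int, str]:
    """Genomic coordinate of the junction-proximal base of an anchor k-mer."""
    chrom, pos, strand = anchor
    if side == "left":  # last base of the 5' flank
        p = pos + k - 1 if strand == "+" else pos
    else:  # first base of the 3' flank
        p = pos if strand == "+" else pos + k - 1
    return chrom, p, strand


def call_candidate(
    profile: KmerProfile,
    brk: Break,
    index: GenomeKmerIndex,
    params: ProfilerParams = ProfilerParams(),
) -> CandidateJunction:
    """Resolve a break's flanking anchors and classify the putative junction.

    Anchors are the nearest mapped k-mers flanking the break; with several
    genomic locations the leftmost (chrom, pos, strand) is taken, which is
    exactly how ambiguous repeats turn into false chimera candidates.
    """
    k = index.k
    li = brk.start - 1
    ri = brk.end + 1
    cand = CandidateJunction(read_id=profile.read_id, brk=brk, left_anchor=None, right_anchor=None)
    if li < 0 or ri >= len(profile):
        return cand  # break touches the read edge: unresolved
    left_locs = index.locations_of_code(int(profile.codes[li]))
    right_locs = index.locations_of_code(int(profile.codes[ri]))
    if not left_locs or not right_locs:
        return cand
    cand.left_anchor = left_locs[0]
    cand.right_anchor = right_locs[0]
    cand.left_mult = int(profile.mult[li])
    cand.right_mult = int(profile.mult[ri])
    cand.chrom_l, cand.pos_l, cand.strand_l = _junction_coords(cand.left_anchor, k, "left")
    cand.chrom_r, cand.pos_r, cand.strand_r = _junction_coords(cand.right_anchor, k, "right")

    if cand.chrom_l != cand.chrom_r:
        cand.category, cand.class_hint = "chimera_candidate", 1
    elif cand.strand_l != cand.strand_r:
        cand.category, cand.class_hint = "chimera_candidate", 3
    else:
        gap = (
            cand.pos_r - cand.pos_l - 1
            if cand.strand_l == "+"
            else cand.pos_l - cand.pos_r - 1
        )
        if gap < 0:
            cand.category, cand.class_hint = "chimera_candidate", 2
        elif params.intron_min <= gap <= params.intron_max:
            cand.category = "splice"
        elif gap > params.readthrough_max:
            cand.category, cand.class_hint = "chimera_candidate", 2
        else:
            # small colinear gap (substitution/indel/error) or read-through
            # distance: not a chimera candidate
            cand.category = "unresolved"
    return cand


class RepeatFlags:
    """Overlap queries against flagged repeat intervals (copies and sources)."""

    def __init__(self, repeats: list[RepeatCopy], k: int):
        self.k = k
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for r in repeats:
            by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
            by_chrom.setdefault(r.src_chrom, []).append((r.src_start, r.src_start + r.length))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for chrom, ivals in by_chrom.items():
            ivals.sort()
            self._starts[chrom] = np.array([a for a, _ in ivals], dtype=np.int64)
            self._ends[chrom] = np.array([b for _, b in ivals], dtype=np.int64)

    def overlaps(self, chrom: str, pos: int) -> bool:
        """Does the k-mer interval [pos, pos+k) overlap any flagged repeat?"""
        starts = self._starts.get(chrom)
        if starts is None:
            return False
        ends = self._ends[chrom]
        i = np.searchsorted(starts, pos + self.k, side="left")
        return bool((ends[:i] > pos).any())


def extract_features(
    cand: CandidateJunction,
    profile: KmerProfile,
    k: int,
    repeat_flags: RepeatFlags | None = None,
) -> dict[str, float]:
    """The eight read-level break features for a chimera candidate.

    Quartiles use linear interpolation between order statistics (the common
    type-7 default). ``mean_amplitude`` is the support drop at the junction:
    mean flank support (up to k mapped positions each side) minus mean
    support inside the break.
    """
    if cand.category != "chimera_candidate":
        raise ValueError("features are defined for chimera candidates only")
    brk = cand.brk
    s = profile.support[brk.start : brk.end + 1].astype(float)
    if s.size == 0:
        raise ValueError("zero-width break")
    q1, q3 = np.percentile(s, [25, 75])
    mapped = profile.mapped
    left_window = np.arange(max(0, brk.start - k), brk.start)
    right_window = np.arange(brk.end + 1, min(len(profile), brk.end + 1 + k))
    flank_idx = np.concatenate([left_window[mapped[left_window]], right_window[mapped[right_window]]])
    flank_support = profile.support[flank_idx].astype(float)
    mean_amp = (flank_support.mean() if flank_support.size else 0.0) - s.mean()

    has_repeat = bool((profile.mult[flank_idx] > 1).any())
    if not has_repeat and repeat_flags is not None:
        for anchor in (cand.left_anchor, cand.right_anchor):
            if anchor and repeat_flags.overlaps(anchor[0], anchor[1]):
                has_repeat = True
                break

    return {
        "score_break_length": brk.width / (k - 1),
        "score_nb_merge": float(brk.n_merged),
        "score_break_variance": float(q3 - q1),
        "score_is_duplicate": 1.0 if (cand.left_mult > 1 or cand.right_mult > 1) else 0.0,
        "score_has_repeat": 1.0 if has_repeat else 0.0,
        "coefficient_variation": float(s.std() / s.mean()),
        "mean_amplitude": float(mean_amp),
        "coefficient_dispersion_interquartile": float((q3 - q1) / (q3 + q1)) if q3 + q1 > 0 else 0.0,
    }


# ---------------------------------------------------------------------------
# Truth labelling
# ---------------------------------------------------------------------------


def junction_matches_truth(
    cand: CandidateJunction, fusion: FusionTruth, tolerance: int
) -> bool:
    """Do the called junction sides match the truth breakpoints (unordered)?"""
    truth5 = (fusion.chrom5, fusion.breakpoint5 - 1)  # last retained 5' base
    truth3 = (fusion.chrom3, fusion.breakpoint3)  # first retained 3' base
    called = [(cand.chrom_l, cand.pos_l), (cand.chrom_r, cand.pos_r)]

    def close(a: tuple[str, int], b: tuple[str, int]) -> bool:
        return a[0] == b[0] and abs(a[1] - b[1]) <= tolerance

    return (close(called[0], truth5) and close(called[1], truth3)) or (
        close(called[1], truth5) and close(called[0], truth3)
    )


def label_candidates(
    candidates: list[CandidateJunction],
    truth: dict[str, tuple[bool, str | None]],
    fusions_by_event: dict[str, FusionTruth],
    tolerance: int = 5,
) -> list[bool]:
    """TRUE iff the read is a truth chimeric read *and* the called junction
    matches the truth breakpoints within tolerance; unknown read ids error."""
    labels = []
    for cand in candidates:
        if cand.read_id not in truth:
            raise KeyError(f"read {cand.read_id} absent from truth")
        is_chimeric, event_id = truth[cand.read_id]
        ok = False
        if is_chimeric and event_id is not None:
            ok = junction_matches_truth(cand, fusions_by_event[event_id], tolerance)
        labels.append(ok)
    return labels


# ---------------------------------------------------------------------------
# Batch pipeline: reads -> labelled feature table
# ---------------------------------------------------------------------------


def build_support(records: list[ReadRecord], k: int) -> SupportTable:
    """Support table over all mates (batch-encoded for constant-length reads)."""
    seqs = [r.mate1_seq for r in records] + [r.mate2_seq for r in records]
    if not seqs:
        return SupportTable([], k)
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        return SupportTable(seqs, k)
    from .kmer import _BASE_TO_CODE

    bases = _BASE_TO_CODE[np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)]
    codes = kmer_codes_2d(bases.reshape(len(seqs), L), k)
    return SupportTable.from_codes(codes, k)


def collect_read_features(
    records: list[ReadRecord],
    index: GenomeKmerIndex,
    support: SupportTable,
    fusions: list[FusionTruth],
    repeats: list[RepeatCopy] | None = None,
    params: ProfilerParams = ProfilerParams(),
    chunk_rows: int = 8192,
) -> pd.DataFrame:
    """Profile every mate, call candidates and emit the labelled feature table.

    One row per chimera candidate: read id, the eight features, the called
    junction sides, the class hint, the truth label and (for truth-chimeric
    reads) the fusion event id. ``break_support`` keeps the raw support
    values inside the break for event-level pooling.
    """
    k = index.k
    fus_by_event = {f.event_id: f for f in fusions}
    repeat_flags = RepeatFlags(repeats, k) if repeats else None

    mate_ids: list[str] = []
    mate_seqs: list[str] = []
    mate_truth: list[tuple[bool, str | None]] = []
    for r in records:
        mate_ids.append(f"{r.read_id}/1")
        mate_seqs.append(r.mate1_seq)
        mate_truth.append((r.junction_offset1 >= 0, r.event_id))
        mate_ids.append(f"{r.read_id}/2")
        mate_seqs.append(r.mate2_seq)
        mate_truth.append((r.junction_offset2 >= 0, r.event_id))

    rows: list[dict] = []
    L = len(mate_seqs[0]) if mate_seqs else 0
    for lo in range(0, len(mate_seqs), chunk_rows):
        hi = min(lo + chunk_rows, len(mate_seqs))
        block = mate_seqs[lo:hi]
        if any(len(s) != L for s in block):
            raise ValueError("collect_read_features expects constant read length")
        bases = np.frombuffer("".join(block).encode("ascii"), dtype=np.uint8)
        from .kmer import _BASE_TO_CODE

        bases = _BASE_TO_CODE[bases].reshape(len(block), L)
        codes = kmer_codes_2d(bases, k)
        # reads overlap heavily, so query unique codes only
        uq, inv = np.unique(codes.ravel(), return_inverse=True)
        mult = index.multiplicity(uq)[inv].reshape(codes.shape)
        supp = support.counts(uq)[inv].reshape(codes.shape)
        has_break = (mult == 0).any(axis=1)
        for ri in np.nonzero(has_break)[0].tolist():
            gi = lo + ri
            prof = KmerProfile(
                read_id=mate_ids[gi],
                seq=mate_seqs[gi],
                codes=codes[ri],
                mult=mult[ri],
                support=supp[ri],
            )
            is_chimeric, event_id = mate_truth[gi]
            for brk in detect_breaks(prof.mapped, params.merge_gap):
                cand = call_candidate(prof, brk, index, params)
                if cand.category != "chimera_candidate":
                    continue
                feats = extract_features(cand, prof, k, repeat_flags)
                label = False
                if is_chimeric and event_id is not None:
                    label = junction_matches_truth(cand, fus_by_event[event_id], params.tolerance)
                row = {
                    "read_id": cand.read_id,
                    **feats,
                    "chrom_l": cand.chrom_l,
                    "pos_l": cand.pos_l,
                    "strand_l": cand.strand_l,
                    "chrom_r": cand.chrom_r,
                    "pos_r": cand.pos_r,
                    "strand_r": cand.strand_r,
                    "class_hint": cand.class_hint,
                    "label": label,
                    "event_id": event_id if (is_chimeric and event_id) else ".",
                    "break_support": prof.support[brk.start : brk.end + 1].tolist(),
                }
                rows.append(row)
    columns = (
        ["read_id"]
        + FEATURES8
        + ["chrom_l", "pos_l", "strand_l", "chrom_r", "pos_r", "strand_r",
           "class_hint", "label", "event_id", "break_support"]
    )
    return pd.DataFrame(rows, columns=columns)
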