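"""Indel calling from Sanger-sequenced amplicon clones.

Each clone sequence is globally aligned to the reference amplicon with an
affine-gap Needleman–Wunsch (Gotoh) aligner, indel runs are normalized to
their leftmost co-optimal placement (the convention used for variant
normalization), and insertion/deletion events near the nuclease cut site
are extracted.  The blunt SpCas9 cut falls 3 bp 5' of the PAM — between
positions 17 and 18 of a 20 nt protospacer — and events whose left edge
lies outside a window around it are treated as clone-borne polymorphisms,
not nuclease products.

Frame classification follows the net length change: a clone with no
in-window events is unedited; an edited clone is in-frame when the summed
insertion-minus-deletion length is a multiple of 3, frameshift otherwise.

Scoring defaults (match +2, mismatch −4, gap open −8, gap extend −1, a
length-k gap scoring open + (k−1)·extend) consolidate scattered changes
into single gap runs, the shape NHEJ alleles actually take.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median
from typing import Sequence

import numpy as np

__all__ = [
    "AlignScoring",
    "Alignment",
    "IndelEvent",
    "CloneCall",
    "CohortProfile",
    "align_to_reference",
    "call_indels",
    "call_clone",
    "classify_frame",
    "summarize_cohort",
    "DEFAULT_WINDOW",
    "MIN_IDENTITY",
]

#: events with left edge within ± this many nt of the cut site are nuclease calls
DEFAULT_WINDOW = 20
#: clones below this aligned identity are flagged unalignable and excluded
MIN_IDENTITY = 0.8

_NEG_INF = -1e30


@dataclass(frozen=True)
class AlignScoring:
    """Affine gap scores; a gap of length k costs gap_open + (k−1)·gap_extend."""

    match: float = 2.0
    mismatch: float = -4.0
    gap_open: float = -8.0
    gap_extend: float = -1.0


@dataclass(frozen=True)
class Alignment:
    """A global alignment as two gapped strings plus its score.

    ``cigar`` runs use '=' (match), 'X' (mismatch), 'I' (insertion relative
    to the reference) and 'D' (deletion of reference bases).
    """

    read_aln: str
    ref_aln: str
    score: float

    @property
    def cigar(self) -> list[tuple[str, int]]:
        ops = []
        for a, b in zip(self.read_aln, self.ref_aln):
            if a == "-":
                op = "D"
            elif b == "-":
                op = "I"
            elif a == b or a == "N" or b == "N":
                op = "="
            else:
                op = "X"
            if ops and ops[-1][0] == op:
                ops[-1][1] += 1
            else:
                ops.append([op, 1])
        return [(op, ln) for op, ln in ops]

    @property
    def identity_fraction(self) -> float:
        n_match = sum(ln for op, ln in self.cigar if op == "=")
        return n_match / len(self.read_aln) if self.read_aln else 0.0


def _score_matrix(read: str, ref: str, sc: AlignScoring) -> np.ndarray:
    """Substitution scores s[i, j] for read[i] vs ref[j]; N is neutral (0)."""
    r = np.frombuffer(read.encode(), dtype=np.uint8)
    q = np.frombuffer(ref.encode(), dtype=np.uint8)
    eq = r[:, None] == q[None, :]
    s = np.where(eq, sc.match, sc.mismatch)
    is_n = (r[:, None] == ord("N")) | (q[None, :] == ord("N"))
    return np.where(is_n, 0.0, s)


def align_to_reference(
    read: str, ref: str, scoring: AlignScoring | None = None
) -> Alignment:
    """Optimal global affine-gap alignment, gaps left-normalized.

    Dynamic programming over three states per cell: M (read base against
    ref base), X (gap in the read, consuming reference = deletion) and Y
    (gap in the reference, consuming read = insertion).  Among co-optimal
    alignments the reported one has every gap run shifted as far left as
    the score allows.
    """
    sc = scoring or AlignScoring()
    read = str(read).strip().upper()
    ref = str(ref).strip().upper()
    if not read or not ref:
        raise ValueError("empty sequence")
    bad = set(read + ref) - set("ACGTN")
    if bad:
        raise ValueError(f"non-ACGTN characters: {sorted(bad)}")

    n, m = len(read), len(ref)
    sub = _score_matrix(read, ref, sc)
    go, ge = sc.gap_open, sc.gap_extend

    M = np.full((n + 1, m + 1), _NEG_INF)
    X = np.full((n + 1, m + 1), _NEG_INF)  # horizontal: gap in read
    Y = np.full((n + 1, m + 1), _NEG_INF)  # vertical: gap in ref
    M[0, 0] = 0.0
    X[0, 1:] = go + ge * np.arange(m)
    Y[1:, 0] = go + ge * np.arange(n)

    for i in range(1, n + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = sub[i - 1] + prev_best[:-1]
        Y[i] = np.maximum(np.maximum(M[i - 1], X[i - 1]) + go, Y[i - 1] + ge)
        Y[i, 0] = go + ge * (i - 1)
        # X[i, j] = max over k<j of max(M[i,k], Y[i,k]) + go + (j-k-1)*ge:
        # a prefix-max scan in the gap-extension gauge
        C = np.maximum(M[i], Y[i]) - ge * np.arange(m + 1)
        run = np.maximum.accumulate(C[:-1])
        X[i, 1:] = run + go + ge * np.arange(1, m + 1) - ge
        X[i, 0] = _NEG_INF

    # traceback (deterministic preference M > X > Y; leftmost placement is
    # restored by the normalization pass below)
    i, j = n, m
    state = max((M[n, m], "M"), (X[n, m], "X"), (Y[n, m], "Y"))[1]
    score = max(M[n, m], X[n, m], Y[n, m])
    ra, fa = [], []  # read-aligned, ref-aligned (built backwards)
    tol = 1e-6
    while i > 0 or j > 0:
        if state == "M":
            ra.append(read[i - 1])
            fa.append(ref[j - 1])
            target = M[i, j] - sub[i - 1, j - 1]
            i, j = i - 1, j - 1
            if abs(M[i, j] - target) < tol:
                state = "M"
            elif abs(X[i, j] - target) < tol:
                state = "X"
            else:
                state = "Y"
        elif state == "X":  # gap in read over ref[j-1]
            ra.append("-")
            fa.append(ref[j - 1])
            here = X[i, j]
            j -= 1
            if j == 0 and i == 0:
                break
            if abs(X[i, j] + ge - here) < tol and j > 0:
                state = "X"
            elif abs(M[i, j] + go - here) < tol:
                state = "M"
            elif abs(Y[i, j] + go - here) < tol:
                state = "Y"
            else:
                state = "X"
        else:  # Y: gap in ref over read[i-1]
            ra.append(read[i - 1])
            fa.append("-")
            here = Y[i, j]
            i -= 1
            if i == 0 and j == 0:
                break
            if abs(Y[i, j] + ge - here) < tol and i > 0:
                state = "Y"
            elif abs(M[i, j] + go - here) < tol:
                state = "M"
            elif abs(X[i, j] + go - here) < tol:
                state = "X"
            else:
                state = "Y"

    read_aln = "".join(reversed(ra))
    ref_aln = "".join(reversed(fa))
    read_aln, ref_aln = _left_normalize(read_aln, ref_aln)
    return Alignment(read_aln=read_aln, ref_aln=ref_aln, score=float(score))


def _left_normalize(a: str, b: str) -> tuple[str, str]:
    """Shift every gap run leftward while the alignment score is unchanged.

    A run of '-' in one row may swap with the base immediately 5' of it
    when the opposing row's bases being re-paired score identically —
    in particular whenever they are equal.  Iterates to a fixpoint.
    """

    def shift(gapped: str, other: str) -> str | None:
        chars = list(gapped)
        moved = False
        i = 0
        L = len(chars)
        while i < L:
            if chars[i] != "-":
                i += 1
                continue
            j = i
            while j < L and chars[j] == "-":
                j += 1
            # run [i, j); try to swap chars[i-1] (a base) into position j-1
            while i > 0 and chars[i - 1] != "-":
                base = chars[i - 1]
                x, y = other[i - 1], other[j - 1]
                if (base == x) != (base == y):
                    break  # re-pairing changes a match into a mismatch or back
                chars[i - 1], chars[j - 1] = "-", base
                i, j = i - 1, j - 1
                moved = True
            i = j + 1
        return "".join(chars) if moved else None

    changed = True
    while changed:
        changed = False
        res = shift(a, b)
        if res is not None:
            a, changed = res, True
        res = shift(b, a)
        if res is not None:
            b, changed = res, True
    return a, b


@dataclass(frozen=True)
class IndelEvent:
    """One insertion or deletion from an aligned clone."""

    clone_id: str
    kind: str  # 'insertion' | 'deletion'
    length: int
    ref_pos: int  # 0-based reference coordinate of the event's left edge
    offset_from_cut: int

    def __post_init__(self) -> None:
        if self.kind not in ("insertion", "deletion"):
            raise ValueError(f"kind must be insertion or deletion, got {self.kind!r}")
        if self.length < 1:
            raise ValueError("event length must be >= 1")


def call_indels(
    alignment: Alignment,
    cut_site: int,
    window: int = DEFAULT_WINDOW,
    clone_id: str = "",
) -> tuple[list[IndelEvent], list[IndelEvent]]:
    """Extract indel events from an alignment, split into (in-window,
    distal) by the event left edge's distance from the cut site."""
    if window < 0:
        raise ValueError("window must be >= 0")
    n_ref = sum(ln for op, ln in alignment.cigar if op in "=XD")
    if not (0 <= cut_site <= n_ref):
        raise ValueError(f"cut_site {cut_site} outside reference [0, {n_ref}]")
    in_window: list[IndelEvent] = []
    distal: list[IndelEvent] = []
    ref_pos = 0
    for op, ln in alignment.cigar:
        if op in ("=", "X"):
            ref_pos += ln
            continue
        kind = "deletion" if op == "D" else "insertion"
        ev = IndelEvent(
            clone_id=clone_id,
            kind=kind,
            length=ln,
            ref_pos=ref_pos,
            offset_from_cut=ref_pos - cut_site,
        )
        (in_window if abs(ev.offset_from_cut) <= window else distal).append(ev)
        if op == "D":
            ref_pos += ln
    return in_window, distal


@dataclass(frozen=True)
class CloneCall:
    """Per-clone result: windowed events, net length change and frame class."""

    clone_id: str
    events: tuple[IndelEvent, ...]
    distal_events: tuple[IndelEvent, ...]
    identity_fraction: float
    unalignable: bool = False

    @property
    def net_length(self) -> int:
        return sum(e.length if e.kind == "insertion" else -e.length for e in self.events)

    @property
    def frame_class(self) -> str:
        return classify_frame(self)


def classify_frame(call: "CloneCall") -> str:
    """unedited (no windowed events) / in_frame (net ≡ 0 mod 3) / frameshift."""
    if not call.events:
        return "unedited"
    return "in_frame" if call.net_length % 3 == 0 else "frameshift"


def call_clone(
    read: str,
    ref: str,
    cut_site: int,
    *,
    window: int = DEFAULT_WINDOW,
    scoring: AlignScoring | None = None,
    clone_id: str = "clone",
    min_identity: float = MIN_IDENTITY,
) -> CloneCall:
    """Align one clone to the reference and call its indels."""
    aln = align_to_reference(read, ref, scoring)
    ident = aln.identity_fraction
    if ident < min_identity:
        return CloneCall(clone_id, (), (), ident, unalignable=True)
    in_win, distal = call_indels(aln, cut_site, window, clone_id)
    return CloneCall(clone_id, tuple(in_win), tuple(distal), ident)


#: indel length bins: 1 bp, 2–8 bp, ≥9 bp (9 bp is grouped with the large bin)
LENGTH_BINS = ("1", "2-8", ">=9")


@dataclass(frozen=True)
class CohortProfile:
    """Cohort-level indel profile over the aligned (non-unalignable) clones."""

    n_clones: int
    n_edited_clones: int
    n_events: int
    deletion_fraction: float
    insertion_fraction: float
    length_bin_counts: dict
    median_indel_length: float
    mean_indel_length: float
    frameshift_fraction: float
    n_unalignable: int = 0

    def to_dict(self) -> dict:
        return {
            "n_clones": self.n_clones,
            "n_edited_clones": self.n_edited_clones,
            "n_events": self.n_events,
            "deletion_fraction": self.deletion_fraction,
            "insertion_fraction": self.insertion_fraction,
            "length_bin_counts": dict(self.length_bin_counts),
            "median_indel_length": self.median_indel_length,
            "mean_indel_length": self.mean_indel_length,
            "frameshift_fraction": self.frameshift_fraction,
            "n_unalignable": self.n_unalignable,
        }


def summarize_cohort(calls: Sequence[CloneCall]) -> CohortProfile:
    """Fig-style cohort summary: deletion/insertion split, length bins
    (1 / 2–8 / ≥9 bp), median and mean event length, and the frameshift
    fraction among edited clones."""
    usable = [c for c in calls if not c.unalignable]
    n_unalignable = len(calls) - len(usable)
    if not usable:
        raise ValueError("no alignable clones in cohort")
    events = [e for c in usable for e in c.events]
    edited = [c for c in usable if c.events]
    n_del = sum(e.kind == "deletion" for e in events)
    bins = {k: 0 for k in LENGTH_BINS}
    for e in events:
        if e.length == 1:
            bins["1"] += 1
        elif e.length <= 8:
            bins["2-8"] += 1
        else:
            bins[">=9"] += 1
    lengths = [e.length for e in events]
    n_fs = sum(c.frame_class == "frameshift" for c in edited)
    return CohortProfile(
        n_clones=len(usable),
        n_edited_clones=len(edited),
        n_events=len(events),
        deletion_fraction=n_del / len(events) if events else 0.0,
        insertion_fraction=(len(events) - n_del) / len(events) if events else 0.0,
        length_bin_counts=bins,
        median_indel_length=float(median(lengths)) if lengths else 0.0,
        mean_indel_length=float(np.mean(lengths)) if lengths else 0.0,
        frameshift_fraction=n_fs / len(edited) if edited else 0.0,
        n_unalignable=n_unalignable,
    )
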