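"""Off-target site enumeration and PAM-proximal windowed mismatch profiling.

Candidate off-target sites are genomic windows adjacent to an NGG PAM whose
ungapped (Hamming) distance to the guide's matched spacer is small.  Because
Cas9 specificity is dominated by the PAM-proximal "seed", mismatches are
profiled in two windows: the full matched length (m20 for a 20 nt guide) and
the 17 PAM-proximal positions (m17) — the window a truncated 17 nt guide
actually pairs with.  The PAM itself, including its unconstrained N, is
never counted as a mismatch.

The module also ships a plain-text fixture of the benchmark on/off-target
site table used throughout the tests: four on-target 20 nt+PAM sites in
EGFP (sites 42, 101, 261 and 379) with 29 candidate genomic off-target
sites and the per-cell-line indel percentages measured for each (``ND`` =
below detection).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import reverse_complement

from .guide_designer import GuideCandidate, _clean_seq

__all__ = [
    "OffTargetHit",
    "CategoryTable",
    "hamming_mismatches",
    "windowed_mismatch_profile",
    "scan_genome",
    "categorize_hits",
    "hits_to_tsv",
    "hits_to_bed",
    "load_table1",
    "validate_table1",
    "annotate_table1_mismatches",
    "SEED_WINDOW",
]

#: PAM-proximal window length (nt) used for the truncated-guide mismatch count.
SEED_WINDOW = 17

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclass(frozen=True)
class OffTargetHit:
    """One candidate genomic site for a guide, PAM excluded from ``site_seq``."""

    guide_name: str
    site_id: str
    record: str
    start: int
    end: int
    strand: str
    site_seq: str
    pam: str
    m20: int
    m17: int

    @property
    def category(self) -> int:
        """Mismatch category: the seed-window count (0 for the on-target)."""
        return 0 if self.m20 == 0 else self.m17


def hamming_mismatches(a: str, b: str) -> int:
    """Positionwise mismatch count between two equal-length DNA strings
    (case-insensitive, ACGT only)."""
    a = _clean_seq(a, allow_n=False)
    b = _clean_seq(b, allow_n=False)
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def windowed_mismatch_profile(
    on_spacer: str, site_seq: str, window: int = SEED_WINDOW
) -> tuple[int, int]:
    """(m_full, m_seed): mismatches over the whole matched length and over
    the ``window`` PAM-proximal positions.

    Both sequences are PAM-excluded spacers written 5'→3' on the guide
    strand, so the PAM-proximal end is the 3' (right) end and the seed
    window is the length-``window`` suffix.
    """
    if len(on_spacer) != len(site_seq):
        raise ValueError("on-target spacer and site must have equal length")
    if len(on_spacer) < window:
        raise ValueError(f"sequences shorter than the {window} nt seed window")
    m_full = hamming_mismatches(on_spacer, site_seq)
    m_seed = hamming_mismatches(on_spacer[-window:], site_seq[-window:])
    return m_full, m_seed


# ---------------------------------------------------------------------------
# genome scanning
# ---------------------------------------------------------------------------


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_ENC[c] for c in seq), dtype=np.uint8, count=len(seq))


def _scan_one_strand(
    codes: np.ndarray, guide_codes: np.ndarray, max_mm: int, pams: Sequence[str]
) -> list[tuple[int, int]]:
    """(pam_pos, n_mismatch) pairs on one already-oriented sequence.

    ``codes`` is read guide-strand 5'→3'; a hit's protospacer occupies
    [pam_pos - L, pam_pos).  N in the genome never matches.
    """
    n, L = len(codes), len(guide_codes)
    if n < L + 3:
        return []
    # PAM positions: match any requested pattern at [p, p+3), N unconstrained
    ok = np.zeros(n - 2, dtype=bool)
    for pat in pams:
        m = np.ones(n - 2, dtype=bool)
        for k, ch in enumerate(pat):
            if ch != "N":
                m &= codes[k : n - 2 + k] == _ENC[ch]
        ok |= m
    pam_pos = np.nonzero(ok)[0]
    pam_pos = pam_pos[pam_pos >= L]
    if pam_pos.size == 0:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)[pam_pos - L]
    mm = (windows != guide_codes).sum(axis=1)  # N (code 4) never equals a base
    keep = mm <= max_mm
    return list(zip(pam_pos[keep].tolist(), mm[keep].tolist()))


def _iter_records(genome) -> Iterable[tuple[str, str]]:
    if isinstance(genome, (str, Path)):
        for rec in SeqIO.parse(str(genome), "fasta"):
            yield rec.id, str(rec.seq)
    else:
        for rec in genome:
            if hasattr(rec, "seq"):
                yield rec.id, str(rec.seq)
            else:  # (name, seq) pairs
                name, seq = rec
                yield name, str(seq)


def scan_genome(
    genome,
    guide: GuideCandidate | str,
    max_mm: int | None = None,
    *,
    include_nag: bool = False,
    seed_window: int = SEED_WINDOW,
    guide_name: str | None = None,
) -> list[OffTargetHit]:
    """Enumerate every NGG-adjacent window within ``max_mm`` ungapped
    mismatches of the guide's matched spacer, on both strands.

    ``genome`` is a FASTA path, an iterable of SeqRecords, or of
    (name, sequence) pairs.  ``max_mm`` defaults to 5 for ≥20 nt guides and
    4 for shorter (truncated) guides — the extremes worth examining at each
    length.  NAG PAMs are off by default.  Hits are unique per
    (record, position, strand) and sorted by (record, start, strand).
    """
    if isinstance(guide, GuideCandidate):
        spacer = guide.matched_spacer
        gname = guide_name or guide.name
    else:
        spacer = _clean_seq(guide, allow_n=False)
        gname = guide_name or "guide"
    L = len(spacer)
    if L < seed_window:
        raise ValueError(f"guide matched length {L} shorter than seed window {seed_window}")
    if max_mm is None:
        max_mm = 5 if L >= 20 else 4
    if max_mm < 0:
        raise ValueError("max_mm must be >= 0")
    pams = ["NGG", "NAG"] if include_nag else ["NGG"]
    gcodes = _encode(spacer)

    hits: list[OffTargetHit] = []
    for rec_name, rec_seq in _iter_records(genome):
        s = _clean_seq(rec_seq)
        codes = _encode(s)
        n = len(s)
        for pam_pos, _ in _scan_one_strand(codes, gcodes, max_mm, pams):
            site = s[pam_pos - L : pam_pos]
            m_full, m_seed = windowed_mismatch_profile(spacer, site, seed_window)
            hits.append(
                OffTargetHit(
                    guide_name=gname,
                    site_id="",
                    record=rec_name,
                    start=pam_pos - L,
                    end=pam_pos,
                    strand="+",
                    site_seq=site,
                    pam=s[pam_pos : pam_pos + 3],
                    m20=m_full,
                    m17=m_seed,
                )
            )
        rc = reverse_complement(s)
        rc_codes = _encode(rc)
        for pam_pos, _ in _scan_one_strand(rc_codes, gcodes, max_mm, pams):
            site = rc[pam_pos - L : pam_pos]
            m_full, m_seed = windowed_mismatch_profile(spacer, site, seed_window)
            # rc index i ↔ sense index n-1-i; protospacer rc [pam_pos-L, pam_pos)
            hits.append(
                OffTargetHit(
                    guide_name=gname,
                    site_id="",
                    record=rec_name,
                    start=n - pam_pos,
                    end=n - pam_pos + L,
                    strand="-",
                    site_seq=site,
                    pam=rc[pam_pos : pam_pos + 3],
                    m20=m_full,
                    m17=m_seed,
                )
            )
    hits.sort(key=lambda h: (h.record, h.start, h.strand))
    hits = [
        OffTargetHit(**{**h.__dict__, "site_id": f"{gname}-hit{i + 1}"})
        for i, h in enumerate(hits)
    ]
    return hits


@dataclass(frozen=True)
class CategoryTable:
    """Counts of candidate hits keyed by seed-window (and full-window)
    mismatch number; exact full-length matches are tallied separately as
    on-target."""

    by_m17: Mapping[int, int]
    by_m20: Mapping[int, int]
    n_on_target: int
    n_candidates: int

    def as_frame(self) -> pd.DataFrame:
        ks = sorted(set(self.by_m17) | set(self.by_m20))
        return pd.DataFrame(
            {
                "mismatches": ks,
                "n_sites_m17": [self.by_m17.get(k, 0) for k in ks],
                "n_sites_m20": [self.by_m20.get(k, 0) for k in ks],
            }
        )


def categorize_hits(hits: Sequence[OffTargetHit]) -> CategoryTable:
    """Partition hits into the seed-window mismatch taxonomy."""
    cand = [h for h in hits if h.m20 > 0]
    by17: dict[int, int] = {}
    by20: dict[int, int] = {}
    for h in cand:
        by17[h.m17] = by17.get(h.m17, 0) + 1
        by20[h.m20] = by20.get(h.m20, 0) + 1
    return CategoryTable(
        by_m17=by17,
        by_m20=by20,
        n_on_target=len(hits) - len(cand),
        n_candidates=len(cand),
    )


def hits_to_tsv(hits: Sequence[OffTargetHit], path) -> None:
    pd.DataFrame(
        [
            {
                "guide": h.guide_name,
                "site_id": h.site_id,
                "record": h.record,
                "start": h.start,
                "end": h.end,
                "strand": h.strand,
                "site_seq": h.site_seq,
                "pam": h.pam,
                "m20": h.m20,
                "m17": h.m17,
            }
            for h in hits
        ]
    ).to_csv(path, sep="\t", index=False)


def hits_to_bed(hits: Sequence[OffTargetHit], path) -> None:
    """BED6: name = site_id, score = seed-window mismatch count."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.record}\t{h.start}\t{h.end}\t{h.site_id}\t{h.m17}\t{h.strand}\n"
            )


# ---------------------------------------------------------------------------
# bundled benchmark site table
# ---------------------------------------------------------------------------

#: measurement columns of the bundled table: (cell line, guide length)
TABLE1_CONDITIONS = [
    ("293T", "20nt"),
    ("293T", "17nt"),
    ("iPSC", "20nt"),
    ("iPSC", "17nt"),
    ("iMSC", "20nt"),
    ("iMSC", "17nt"),
]


def load_table1(path=None) -> pd.DataFrame:
    """Load the bundled on/off-target benchmark table.

    Columns added on load: ``guide`` (site family, e.g. sgGFP42),
    ``is_on_target``, ``seq20``/``pam20`` and ``seq17``/``pam17`` (spacer
    split from the printed spacer+PAM string; the PAM's N is lowercase as
    printed).  Measurement columns keep ``ND`` as NaN with a parallel
    ``*_nd`` boolean.
    """
    if path is None:
        ref = resources.files("truncguide").joinpath("data/table1_sites.tsv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", dtype=str)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
    df["guide"] = df["target_id"].str.split("-").str[0]
    df["is_on_target"] = df["target_id"].str.endswith("-On")
    df["seq20"] = df["seq20_pam"].str[:-3].str.upper()
    df["pam20"] = df["seq20_pam"].str[-3:]
    df["seq17"] = df["seq17_pam"].str[:-3].str.upper()
    df["pam17"] = df["seq17_pam"].str[-3:]
    for cell, length in TABLE1_CONDITIONS:
        col = f"indel_{cell}_{length}"
        df[f"{col}_nd"] = df[col] == "ND"
        df[col] = pd.to_numeric(df[col].replace("ND", None))
    return df


def validate_table1(df: pd.DataFrame) -> None:
    """Structural integrity checks on the benchmark table; raises on failure."""
    n_on = int(df["is_on_target"].sum())
    n_off = int((~df["is_on_target"]).sum())
    if n_on != 4 or n_off != 29:
        raise ValueError(f"expected 4 on-target and 29 candidate rows, got {n_on}/{n_off}")
    for _, row in df.iterrows():
        pam = row["pam20"].upper()
        if pam[1:] != "GG" or row["pam17"].upper()[1:] != "GG":
            raise ValueError(f"{row['target_id']}: PAM does not match NGG")
        if (row["seq17"] + row["pam17"].upper()) != (row["seq20"] + pam)[-20:]:
            raise ValueError(
                f"{row['target_id']}: 17 nt sequence is not the PAM-proximal "
                "suffix of the 20 nt sequence"
            )


def annotate_table1_mismatches(df: pd.DataFrame) -> pd.DataFrame:
    """Add m20/m17 per row, comparing each site against its family's
    on-target spacer (on-target rows score 0/0)."""
    on = df[df["is_on_target"]].set_index("guide")["seq20"]
    m20, m17 = [], []
    for _, row in df.iterrows():
        full, seed = windowed_mismatch_profile(on[row["guide"]], row["seq20"])
        m20.append(full)
        m17.append(seed)
    out = df.copy()
    out["m20"] = m20
    out["m17"] = m17
    return out
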