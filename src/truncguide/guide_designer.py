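"""Design of SpCas9 guides at full (20 nt) and truncated (16–19 nt) spacer lengths.

A protospacer is the genomic sequence immediately 5' of an NGG PAM on the
guide's strand.  Guides are designed at a requested *matched* spacer length
(the number of genome-complementary positions).  Because the human U6
promoter initiates transcription on a guanine, a spacer whose genomic 5'
base is not G may instead carry a single mismatched guanine tag (written as
a lowercase ``g``); the tag is not genome-matched and does not count toward
the matched length.

Effectiveness rule: a guide is expected to be active only if its matched
length is at least 17 nt, and, when it carries a mismatched 5' g, only if
its total length (tag included) is at least 18 nt.

Coordinates are 0-based, half-open, on the sense strand of the input
sequence.  A minus-strand guide's protospacer still occupies a sense-strand
interval [start, start+L); its spacer is reported 5'→3' on the guide
strand, i.e. as the reverse complement of that interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from Bio.Seq import reverse_complement

__all__ = [
    "GuideCandidate",
    "CloningOligoSet",
    "PamSite",
    "find_pam_sites",
    "design_guides",
    "truncate_guide",
    "build_cloning_oligos",
    "guides_to_tsv",
    "SGRNA_TEMPLATE_LEFT",
    "SGRNA_TEMPLATE_RIGHT",
    "SGRNA_FWD_PRIMER",
    "SGRNA_REV_PRIMER",
]

#: Gibson-assembly scaffold flanking the N16–19 spacer insert.  The trailing
#: ...ACACCG of the left arm supplies the spacer's leading G.
SGRNA_TEMPLATE_LEFT = "TATATATCTTGTGGAAAGGACGAAACACCG"
SGRNA_TEMPLATE_RIGHT = "GTTTTAGAGCTAGAAATAGCAAGTTAAAAT"
SGRNA_FWD_PRIMER = "TATATATCTTGTGGAAAGGACGAA"
SGRNA_REV_PRIMER = "ATTTTAACTTGCTATTTCTAGCTCTAA"

MIN_SPACER_LEN = 16
MAX_SPACER_LEN = 20

_VALID = set("ACGTN")


def _clean_seq(seq: str, *, allow_n: bool = True) -> str:
    s = str(seq).strip().upper()
    allowed = _VALID if allow_n else _VALID - {"N"}
    bad = set(s) - allowed
    if bad:
        raise ValueError(
            f"sequence contains characters outside {'ACGTN' if allow_n else 'ACGT'}: "
            f"{sorted(bad)}"
        )
    return s


@dataclass(frozen=True)
class PamSite:
    """An NGG occurrence; ``pos`` is the sense-strand index of the PAM
    triplet's leftmost base (the N for '+' sites; for '−' sites the sense
    strand reads CCN at [pos, pos+3))."""

    pos: int
    strand: str

    def __iter__(self):  # tuple-like unpacking: (pos, strand)
        return iter((self.pos, self.strand))


@dataclass(frozen=True)
class GuideCandidate:
    """A designed spacer and its genomic context.

    ``spacer`` is written 5'→3' on the guide strand; a mismatched 5' tag is
    lowercase ``g``.  ``start`` is the sense-strand coordinate of the
    leftmost matched protospacer base; ``site_label`` is the 1-based sense
    position of the spacer's 5'-most matched base (strand aware), the
    convention used for names like "site 42".
    """

    name: str
    spacer: str
    matched_len: int
    total_len: int
    pam: str
    strand: str
    start: int
    site_label: int
    five_prime_tagged: bool
    three_prime_pref: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (MIN_SPACER_LEN <= self.matched_len <= MAX_SPACER_LEN):
            raise ValueError(f"matched_len {self.matched_len} outside [16, 20]")
        expected_total = self.matched_len + (1 if self.five_prime_tagged else 0)
        if self.total_len != expected_total:
            raise ValueError("total_len inconsistent with matched_len and tag")
        if len(self.spacer) != self.total_len:
            raise ValueError("spacer length inconsistent with total_len")
        pam = self.pam.upper()
        if len(pam) != 3 or pam[1:] != "GG":
            raise ValueError(f"PAM {self.pam!r} does not match NGG")

    @property
    def matched_spacer(self) -> str:
        """The genome-matched spacer, uppercase, tag removed."""
        s = self.spacer[1:] if self.five_prime_tagged else self.spacer
        return s.upper()

    @property
    def effective_flag(self) -> bool:
        """Expected-effective per the minimum-length rules (17 nt matched;
        18 nt total when 5'-g-tagged)."""
        if self.matched_len < 17:
            return False
        if self.five_prime_tagged and self.total_len < 18:
            return False
        return True

    @property
    def end(self) -> int:
        """Sense-strand end (exclusive) of the matched protospacer."""
        return self.start + self.matched_len

    @property
    def cut_site(self) -> int:
        """Sense-strand coordinate of the blunt SpCas9 cut, which falls
        between positions ``cut_site-1`` and ``cut_site`` (3 bp 5' of the
        PAM on the guide strand)."""
        if self.strand == "+":
            return self.end - 3
        return self.start + 3


@dataclass(frozen=True)
class CloningOligoSet:
    """Gibson-assembly synthesis template and amplification primers for one
    guide insert."""

    template: str
    insert: str
    fwd_primer: str = SGRNA_FWD_PRIMER
    rev_primer: str = SGRNA_REV_PRIMER

    def __post_init__(self) -> None:
        if not (16 <= len(self.insert) <= 19):
            raise ValueError(f"insert length {len(self.insert)} outside N16–19")
        if self.template != SGRNA_TEMPLATE_LEFT + self.insert + SGRNA_TEMPLATE_RIGHT:
            raise ValueError("template does not match scaffold + insert + scaffold")


def find_pam_sites(
    seq: str,
    strands: Iterable[str] = ("+", "-"),
    *,
    min_flank: int = 0,
) -> list[PamSite]:
    """Exhaustively locate NGG PAMs on the requested strands.

    ``min_flank`` drops PAMs without at least that much protospacer room 5'
    of the PAM on the guide strand (0 keeps every NGG).  N never matches.
    """
    s = _clean_seq(seq)
    strands = set(strands)
    if not strands <= {"+", "-"}:
        raise ValueError(f"strands must be a subset of {{'+','-'}}, got {strands}")
    n = len(s)
    out: list[PamSite] = []
    for p in range(n - 2):
        if "+" in strands and s[p + 1] == "G" and s[p + 2] == "G":
            if p >= min_flank:
                out.append(PamSite(p, "+"))
        # guide-strand NGG on '−' appears as CCN on the sense strand
        if "-" in strands and s[p] == "C" and s[p + 1] == "C":
            if (n - (p + 3)) >= min_flank:
                out.append(PamSite(p, "-"))
    return out


def _protospacer_at(seq: str, pam: PamSite, length: int) -> tuple[str, str, int] | None:
    """Matched protospacer (guide strand 5'→3'), PAM 3-mer and sense start
    for a PAM site, or None when the flank is too short or overlaps N."""
    if pam.strand == "+":
        start = pam.pos - length
        if start < 0:
            return None
        proto = seq[start : pam.pos]
        pam3 = seq[pam.pos : pam.pos + 3]
    else:
        start = pam.pos + 3
        if start + length > len(seq):
            return None
        proto = reverse_complement(seq[start : start + length])
        pam3 = reverse_complement(seq[pam.pos : pam.pos + 3])
    if "N" in proto or "N" in pam3[1:]:
        return None
    return proto, pam3, start


def design_guides(
    seq: str,
    spacer_len: int,
    policy: str = "any",
    *,
    strands: Iterable[str] = ("+", "-"),
    name_prefix: str = "guide",
    site_label_offset: int = 0,
) -> list[GuideCandidate]:
    """Enumerate one guide candidate per designable NGG site.

    policy:
      ``require_matched_G`` — emit only protospacers whose genomic 5' base
        is G (U6-compatible without a tag);
      ``prepend_g`` — tag a lowercase mismatched g onto protospacers whose
        5' base is not G (total length grows by one);
      ``any`` — emit every protospacer untagged, regardless of 5' base.

    ``site_label_offset`` shifts the reported 1-based site label, for
    matching an external numbering convention.
    """
    if policy not in ("require_matched_G", "prepend_g", "any"):
        raise ValueError(f"unknown policy {policy!r}")
    if not (MIN_SPACER_LEN <= spacer_len <= MAX_SPACER_LEN):
        raise ValueError(f"spacer_len {spacer_len} outside [16, 20]")
    s = _clean_seq(seq)
    if not s:
        raise ValueError("empty sequence")

    guides: list[GuideCandidate] = []
    skipped_n = 0
    for pam in find_pam_sites(s, strands):
        got = _protospacer_at(s, pam, spacer_len)
        if got is None:
            if _protospacer_at(s.replace("N", "A"), pam, spacer_len) is not None:
                skipped_n += 1  # flank exists but overlaps an ambiguity code
            continue
        proto, pam3, start = got
        tagged = False
        spacer = proto
        if proto[0] != "G":
            if policy == "require_matched_G":
                continue
            if policy == "prepend_g":
                spacer = "g" + proto
                tagged = True
        # 5'-most matched base on the guide strand, 1-based sense position
        label = (start + 1) if pam.strand == "+" else (start + spacer_len)
        label += site_label_offset
        guides.append(
            GuideCandidate(
                name=f"{name_prefix}_{label}{pam.strand}",
                spacer=spacer,
                matched_len=spacer_len,
                total_len=len(spacer),
                pam=pam3,
                strand=pam.strand,
                start=start,
                site_label=label,
                five_prime_tagged=tagged,
                three_prime_pref=proto[-1] in "GA",
            )
        )
    if skipped_n:
        warnings.warn(
            f"{skipped_n} PAM site(s) skipped: protospacer or PAM overlaps N",
            stacklevel=2,
        )
    return guides


def truncate_guide(g20: GuideCandidate, new_len: int) -> GuideCandidate:
    """Shorten an untagged guide to its PAM-proximal ``new_len`` suffix.

    PAM, strand and site are unchanged; only the PAM-distal end is trimmed,
    so the truncated guide targets the same cut site.
    """
    if g20.five_prime_tagged:
        raise ValueError("cannot truncate a g-tagged guide; truncate the untagged parent")
    if new_len > g20.matched_len:
        raise ValueError(f"new_len {new_len} exceeds matched length {g20.matched_len}")
    if new_len < MIN_SPACER_LEN:
        raise ValueError(f"new_len {new_len} below minimum spacer length {MIN_SPACER_LEN}")
    if new_len == g20.matched_len:
        return g20
    # the spacer's 3' end is PAM-proximal, so truncation keeps the suffix
    spacer = g20.spacer[-new_len:]
    # '+': protospacer loses its leftmost (PAM-distal) sense bases;
    # '−': the PAM-distal end is the rightmost sense base, start unchanged
    start = g20.start + (g20.matched_len - new_len) if g20.strand == "+" else g20.start
    return replace(
        g20,
        spacer=spacer,
        matched_len=new_len,
        total_len=new_len,
        start=start,
    )


def build_cloning_oligos(g: GuideCandidate) -> CloningOligoSet:
    """Synthesis template and primers for cloning one guide.

    The scaffold's trailing ...ACACCG supplies the spacer's leading G, so
    the insert is the spacer minus that guanine (matched G or mismatched g
    alike).
    """
    if not g.spacer or g.spacer[0].upper() != "G":
        raise ValueError(
            "spacer must begin with G/g for the U6 scaffold; redesign with "
            "policy='prepend_g' to tag a mismatched g"
        )
    insert = g.spacer[1:].upper()
    return CloningOligoSet(
        template=SGRNA_TEMPLATE_LEFT + insert + SGRNA_TEMPLATE_RIGHT,
        insert=insert,
    )


def guides_to_tsv(guides: Sequence[GuideCandidate], path) -> None:
    """Write the designer's tabular output (one row per candidate)."""
    import pandas as pd

    pd.DataFrame(
        [
            {
                "name": g.name,
                "site_label": g.site_label,
                "strand": g.strand,
                "start": g.start,
                "spacer": g.spacer,
                "matched_len": g.matched_len,
                "total_len": g.total_len,
                "pam": g.pam,
                "three_prime_pref": g.three_prime_pref,
                "effective_flag": g.effective_flag,
            }
            for g in guides
        ]
    ).to_csv(path, sep="\t", index=False)
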