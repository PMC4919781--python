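"""Seeded generators for every input the pipeline consumes.

These stand in for the wet-lab artifacts: Sanger-cloned edited amplicons
(a deletion-dominated NHEJ indel spectrum), genomes with planted
off-target sites at chosen seed-window mismatch counts, binomially sampled
reporter-negative FACS populations, and T7E1 cleavage fractions consistent
with a known true indel rate.  Every generator takes an explicit seed (or
a numpy Generator) and is bit-reproducible; each returns its ground truth
alongside the data so recovery can be checked exactly.

Defaults describe the study conditions the pipeline is meant to analyse:
~80% of NHEJ events are deletions with a geometric-like length spectrum of
mean ≈ 5 nt (support 1–30 nt), the unedited reporter background is 0.5%
GFP-negative, and FACS samples count 10⁴–10⁶ cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq, reverse_complement
from Bio.SeqRecord import SeqRecord

from .guide_designer import GuideCandidate
from .ko_stats import KORecord
from .offtarget_scanner import SEED_WINDOW, windowed_mismatch_profile
from .t7e1_quant import FC_CLAMP, T7E1Measurement, invert_indel_percent

__all__ = [
    "IndelSpectrum",
    "simulate_edited_reads",
    "plant_offtarget_genome",
    "simulate_facs",
    "simulate_t7e1",
    "random_dna",
    "write_fasta",
    "truth_to_bed",
]

_BASES = np.array(list("ACGT"))


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def random_dna(length: int, seed, gc: float = 0.5) -> str:
    """Random background sequence; ``gc`` sets the G+C fraction."""
    rng = _rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def _geometric_lengths(mean: float, support: int) -> np.ndarray:
    """Truncated-geometric pmf on 1..support with approximately the given mean."""
    p = 1.0 / mean
    k = np.arange(1, support + 1)
    w = (1 - p) ** (k - 1) * p
    return w / w.sum()


@dataclass(frozen=True)
class IndelSpectrum:
    """Parameters of the simulated NHEJ event distribution (emulation
    parameters, not measurements)."""

    p_deletion: float = 0.8
    length_probs: tuple[float, ...] = tuple(_geometric_lengths(5.0, 30))
    complex_allele_rate: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_deletion <= 1.0):
            raise ValueError("p_deletion outside [0, 1]")
        if abs(sum(self.length_probs) - 1.0) > 1e-9:
            raise ValueError("length probabilities must sum to 1")

    @property
    def max_length(self) -> int:
        return len(self.length_probs)

    def sample_event(self, rng: np.random.Generator) -> tuple[str, int]:
        kind = "deletion" if rng.random() < self.p_deletion else "insertion"
        length = int(rng.choice(self.max_length, p=np.asarray(self.length_probs))) + 1
        return kind, length


def _apply_events(ref: str, events: Sequence[tuple[str, int, int]], rng) -> str:
    """Apply (kind, length, left_edge) events to a reference, right to left."""
    s = ref
    for kind, length, pos in sorted(events, key=lambda e: -e[2]):
        if kind == "deletion":
            s = s[:pos] + s[pos + length :]
        else:
            ins = "".join(rng.choice(_BASES, size=length))
            s = s[:pos] + ins + s[pos:]
    return s


def simulate_edited_reads(
    ref: str,
    cut_site: int,
    n_reads: int,
    edit_rate: float,
    spectrum: IndelSpectrum | None = None,
    seed=None,
    *,
    placement_jitter: int = 8,
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Simulate Sanger-style clone sequences from an edited cell pool.

    Each read is independently edited with probability ``edit_rate``; an
    edited read carries one NHEJ event at the cut site (or two nearby
    events, at the spectrum's complex-allele rate).  Deletion left edges
    are jittered within ``placement_jitter`` nt of the cut so events stay
    inside the caller's window.  Returns (reads, truth table).
    """
    spectrum = spectrum or IndelSpectrum()
    if not (0.0 <= edit_rate <= 1.0):
        raise ValueError("edit_rate outside [0, 1]")
    # a complex allele can extend a second event ~2 event-lengths 3' of the cut
    margin = 2 * spectrum.max_length + placement_jitter + 8
    if cut_site < placement_jitter + 2 or cut_site > len(ref) - margin:
        raise ValueError(
            f"cut site {cut_site} too close to the reference edge for events "
            f"up to {spectrum.max_length} nt"
        )
    rng = _rng(seed)
    ref = str(ref).upper()
    reads: list[SeqRecord] = []
    truth_rows = []
    for k in range(n_reads):
        clone_id = f"clone{k:04d}"
        edited = rng.random() < edit_rate
        events: list[tuple[str, int, int]] = []
        if edited:
            n_events = 2 if rng.random() < spectrum.complex_allele_rate else 1
            anchor = cut_site
            for _ in range(n_events):
                kind, length = spectrum.sample_event(rng)
                if kind == "deletion":
                    lo = max(0, min(length - 1, placement_jitter))
                    pos = anchor - int(rng.integers(0, lo + 1))
                else:
                    pos = anchor
                events.append((kind, length, pos))
                # a second event lands 3' of the first, non-overlapping
                anchor = max(a[2] + (a[1] if a[0] == "deletion" else 0) for a in events) + 3
        seq = _apply_events(ref, events, rng)
        reads.append(SeqRecord(Seq(seq), id=clone_id, description=""))
        net = sum(ln if kd == "insertion" else -ln for kd, ln, _ in events)
        truth_rows.append(
            {
                "clone_id": clone_id,
                "edited": edited,
                "n_events": len(events),
                "kinds": ",".join(e[0] for e in events),
                "lengths": ",".join(str(e[1]) for e in events),
                "positions": ",".join(str(e[2]) for e in events),
                "net_length": net,
                "frame_class": "unedited"
                if not events
                else ("in_frame" if net % 3 == 0 else "frameshift"),
            }
        )
    return reads, pd.DataFrame(truth_rows)


def plant_offtarget_genome(
    guide: GuideCandidate | str,
    plan: Mapping[int, int],
    background_len: int = 50_000,
    seed=None,
    *,
    extra_distal_mm: int = 0,
    seed_window: int = SEED_WINDOW,
    gc: float = 0.5,
    record_name: str = "chrSyn",
) -> tuple[SeqRecord, pd.DataFrame]:
    """Random genome with NGG-adjacent sites planted at exact seed-window
    mismatch counts.

    ``plan`` maps a seed-window mismatch count to the number of sites to
    plant (0 plants the exact on-target locus).  Mismatch positions are
    drawn uniformly within the PAM-proximal window; ``extra_distal_mm``
    adds PAM-distal mismatches so the full-window count exceeds the seed
    count.  Sites are placed non-overlapping on random strands.  Returns
    the genome record and a truth table with BED-compatible coordinates.
    """
    spacer = guide.matched_spacer if isinstance(guide, GuideCandidate) else str(guide).upper()
    L = len(spacer)
    if seed_window > L:
        raise ValueError("seed window longer than the guide spacer")
    for m in plan:
        if m < 0 or m > seed_window:
            raise ValueError(f"infeasible plan: {m} mismatches in a {seed_window} nt window")
    if extra_distal_mm > L - seed_window:
        raise ValueError("more distal mismatches than PAM-distal positions")
    rng = _rng(seed)
    n_sites = sum(plan.values())
    footprint = L + 3
    slot = footprint + 20  # guard gap between planted sites
    if background_len < n_sites * slot + 2 * slot:
        raise ValueError("background too short to hold all planted sites")

    genome = list(random_dna(background_len, rng, gc=gc))
    positions = (np.arange(n_sites) + 1) * (background_len // (n_sites + 2))
    seed_positions = list(range(L - seed_window, L))
    distal_positions = list(range(0, L - seed_window))

    truth_rows = []
    idx = 0
    for m, count in sorted(plan.items()):
        for _ in range(count):
            site = list(spacer)
            mm_at = rng.choice(seed_positions, size=m, replace=False) if m else []
            for p in mm_at:
                site[p] = rng.choice([b for b in "ACGT" if b != site[p]])
            if extra_distal_mm:
                for p in rng.choice(distal_positions, size=extra_distal_mm, replace=False):
                    site[p] = rng.choice([b for b in "ACGT" if b != site[p]])
            site_seq = "".join(site)
            pam = str(rng.choice(_BASES)) + "GG"
            strand = "+" if rng.random() < 0.5 else "-"
            insert = site_seq + pam if strand == "+" else reverse_complement(site_seq + pam)
            pos = int(positions[idx])
            genome[pos : pos + footprint] = list(insert)
            start = pos if strand == "+" else pos + 3
            m_full, m_seed = windowed_mismatch_profile(spacer, site_seq, seed_window)
            assert m_seed == m  # planting is exact by construction
            truth_rows.append(
                {
                    "record": record_name,
                    "start": start,
                    "end": start + L,
                    "strand": strand,
                    "site_seq": site_seq,
                    "pam": pam,
                    "m17": m_seed,
                    "m20": m_full,
                }
            )
            idx += 1
    rec = SeqRecord(Seq("".join(genome)), id=record_name, description="synthetic")
    truth = pd.DataFrame(
        truth_rows,
        columns=["record", "start", "end", "strand", "site_seq", "pam", "m17", "m20"],
    ).sort_values(["record", "start", "strand"], ignore_index=True)
    return rec, truth


def simulate_facs(
    true_ko: float,
    n_cells: int,
    background_neg: float = 0.005,
    seed=None,
    *,
    cell_line: str = "sim",
    guide_name: str = "sim",
    spacer_class: str = "20nt",
    replicate: int = 1,
) -> KORecord:
    """Binomial FACS readout: a cell is reporter-negative if knocked out or,
    otherwise, with the background-negative probability, so
    P(neg) = θ + (1 − θ)·bg."""
    if not (0.0 <= true_ko <= 1.0 and 0.0 <= background_neg <= 1.0):
        raise ValueError("proportions outside [0, 1]")
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    rng = _rng(seed)
    p_neg = true_ko + (1.0 - true_ko) * background_neg
    n_neg = int(rng.binomial(n_cells, p_neg))
    return KORecord(
        cell_line=cell_line,
        guide_name=guide_name,
        spacer_class=spacer_class,
        replicate=replicate,
        n_total=n_cells,
        n_gfp_neg=n_neg,
    )


def simulate_t7e1(
    true_indel_pct: float,
    noise_sd: float = 0.02,
    seed=None,
    *,
    site_id: str = "sim",
    nd_threshold: float = 2.0,
) -> T7E1Measurement:
    """Noisy T7E1 readout of a known indel rate: the implied cleavage
    fraction plus Gaussian densitometry noise, truncated to [0, ~1)."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = _rng(seed)
    fc = invert_indel_percent(true_indel_pct) + rng.normal(0.0, noise_sd)
    fc = float(min(max(fc, 0.0), FC_CLAMP))
    return T7E1Measurement.from_fraction(site_id, fc, nd_threshold, clamp=True)


def write_fasta(records: Sequence[SeqRecord], path) -> None:
    from Bio import SeqIO

    SeqIO.write(records, str(path), "fasta")


def truth_to_bed(truth: pd.DataFrame, path) -> None:
    """BED6 of planted sites (score = seed-window mismatch count)."""
    with open(path, "w") as fh:
        for i, r in truth.iterrows():
            fh.write(
                f"{r['record']}\t{r['start']}\t{r['end']}\tplanted{i}\t{r['m17']}\t{r['strand']}\n"
            )
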