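"""Ancient-DNA damage authentication.

Cytosine deamination accumulates at fragment termini over burial time and
is read out as C→T substitutions at the 5' end (and, in double-stranded
libraries, G→A at the 3' end). This module tallies positional
substitution spectra from alignment hits, classifies single reads as
ancient / default / rejected, summarises per-(sample, taxon) damage
proportions, and fits the geometric decay model ``f(i) = d * r**i + eps``
to a spectrum for parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .align import AlignmentHit

DEFAULT_SPECTRUM_POSITIONS = 20
DEFAULT_TERMINAL_WINDOW = 5
DEFAULT_MIN_READS = 50       # below this a damage proportion is low-confidence
DEFAULT_STRINGENT_MIN_PID = 0.95
DEFAULT_STRINGENT_MAX_GAP_FRAC = 0.1


@dataclass
class DamageSpectrum:
    """Positional damage frequencies with their denominators.

    ``f5[i]`` is the C→T rate among alignment columns whose reference
    base is C at 5' position i; ``f3[j]`` the G→A rate at position j from
    the 3' end. Positions with zero denominator are NaN (undefined).
    ``other_rate`` is the pooled rate of all other substitution types
    (the background).
    """

    f5: np.ndarray
    f3: np.ndarray
    n5: np.ndarray
    n3: np.ndarray
    other_rate: float
    n_hits: int

    def defined5(self) -> np.ndarray:
        return self.n5 > 0

    def to_frame(self) -> pd.DataFrame:
        m = len(self.f5)
        return pd.DataFrame(
            {
                "position": np.arange(m),
                "f5_CT": self.f5,
                "n5_refC": self.n5,
                "f3_GA": self.f3,
                "n3_refG": self.n3,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class ReadDamageCall:
    read_id: str
    sample_id: str
    taxon_id: int
    call: str  # ancient | default | rejected
    evidence: tuple[tuple[int, str], ...] = ()

    def __post_init__(self):
        if self.call == "ancient" and not self.evidence:
            raise ValueError("ancient call requires damage evidence")


def _ref_base_at(hit: AlignmentHit, read_sequence: str) -> dict[int, str]:
    """Reference base per read position (read orientation).

    Matched positions carry the read base; mismatched positions the
    recorded reference base; read positions aligned to a reference gap
    have no reference base and are excluded.
    """
    bases = {i: read_sequence[i] for i in range(len(read_sequence))}
    for pos, ref_base, _ in hit.mismatches:
        bases[pos] = ref_base
    for pos in hit.read_insertions:
        bases.pop(pos, None)
    return bases


def substitution_spectrum(
    hits: Sequence[AlignmentHit],
    reads: Mapping[str, str],
    m: int = DEFAULT_SPECTRUM_POSITIONS,
) -> DamageSpectrum:
    """Tally C→T by 5' position and G→A by 3' position over ``m`` positions.

    ``reads`` maps read_id to the read sequence (needed to recover
    reference bases at matched columns). Other substitution types pool
    into a single background rate.
    """
    c5 = np.zeros(m, dtype=np.int64)
    n5 = np.zeros(m, dtype=np.int64)
    c3 = np.zeros(m, dtype=np.int64)
    n3 = np.zeros(m, dtype=np.int64)
    other = 0
    columns = 0
    for hit in hits:
        seq = reads[hit.read_id]
        L = len(seq)
        ref_bases = _ref_base_at(hit, seq)
        mm = {pos: (rb, qb) for pos, rb, qb in hit.mismatches}
        for pos, ref_base in ref_bases.items():
            columns += 1
            j = L - 1 - pos
            is_ct = pos in mm and mm[pos] == ("C", "T")
            is_ga = pos in mm and mm[pos] == ("G", "A")
            if ref_base == "C" and pos < m:
                n5[pos] += 1
                if is_ct:
                    c5[pos] += 1
            if ref_base == "G" and j < m:
                n3[j] += 1
                if is_ga:
                    c3[j] += 1
            if pos in mm and not is_ct and not is_ga:
                other += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        f5 = np.where(n5 > 0, c5 / np.maximum(n5, 1), np.nan)
        f3 = np.where(n3 > 0, c3 / np.maximum(n3, 1), np.nan)
    return DamageSpectrum(
        f5=f5,
        f3=f3,
        n5=n5,
        n3=n3,
        other_rate=other / columns if columns else 0.0,
        n_hits=len(hits),
    )


def classify_read(
    hit: AlignmentHit,
    sample_id: str,
    taxon_id: int | None = None,
    k_terminal: int = DEFAULT_TERMINAL_WINDOW,
    min_pid: float = DEFAULT_STRINGENT_MIN_PID,
    max_gap_frac: float = DEFAULT_STRINGENT_MAX_GAP_FRAC,
) -> ReadDamageCall:
    """Ancient / default / rejected call for one best-hit read.

    Rejected if the hit fails the stringent gate (identity, gap
    fraction); otherwise ancient iff at least one C→T mismatch lies
    within the first ``k_terminal`` 5' positions or one G→A within the
    last ``k_terminal`` 3' positions.
    """
    taxon = hit.taxon_id if taxon_id is None else taxon_id
    if hit.identity < min_pid or (
        hit.columns and hit.gaps / hit.columns > max_gap_frac
    ):
        return ReadDamageCall(hit.read_id, sample_id, taxon, "rejected")
    L = hit.read_length
    evidence = []
    for pos, ref_base, read_base in hit.mismatches:
        if ref_base == "C" and read_base == "T" and pos < k_terminal:
            evidence.append((pos, "C>T"))
        elif ref_base == "G" and read_base == "A" and pos >= L - k_terminal:
            evidence.append((pos, "G>A"))
    if evidence:
        return ReadDamageCall(hit.read_id, sample_id, taxon, "ancient", tuple(evidence))
    return ReadDamageCall(hit.read_id, sample_id, taxon, "default")


@dataclass
class DamageSummary:
    """Per-(sample, taxon) damage proportions."""

    table: pd.DataFrame  # columns: sample_id, taxon_id, n_ancient, n_default, proportion, low_confidence

    def per_sample(self) -> pd.Series:
        """Pooled damage proportion per sample (all taxa together)."""
        g = self.table.groupby("sample_id")[["n_ancient", "n_default"]].sum()
        totals = g.sum(axis=1)
        return (g["n_ancient"] / totals.where(totals > 0)).rename("proportion")

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def damage_proportion(
    calls: Iterable[ReadDamageCall], min_reads: int = DEFAULT_MIN_READS
) -> DamageSummary:
    """Proportion ancient / (ancient + default) per (sample, taxon).

    Rejected reads are excluded from the denominator. Groups with fewer
    than ``min_reads`` retained reads are flagged low-confidence but
    still reported (single-read groups included); groups with no
    retained reads get an undefined (NaN) proportion.
    """
    grouped: dict[tuple[str, int], dict[str, int]] = {}
    for call in calls:
        key = (call.sample_id, call.taxon_id)
        row = grouped.setdefault(key, {"ancient": 0, "default": 0, "rejected": 0})
        row[call.call] += 1
    rows = []
    for (sample_id, taxon_id), row in sorted(grouped.items()):
        total = row["ancient"] + row["default"]
        proportion = row["ancient"] / total if total else np.nan
        rows.append(
            (
                sample_id,
                taxon_id,
                row["ancient"],
                row["default"],
                row["rejected"],
                proportion,
                total < min_reads,
            )
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "sample_id", "taxon_id", "n_ancient", "n_default", "n_rejected",
            "proportion", "low_confidence",
        ],
    )
    return DamageSummary(table)


@dataclass(frozen=True)
class DecayFit:
    d_hat: float
    r_hat: float
    eps_hat: float
    rss: float
    n_positions: int
    degenerate: bool = False  # all-zero spectrum; r_hat is meaningless


def fit_decay(spectrum: DamageSpectrum) -> DecayFit:
    """Least-squares fit of ``f5[i] ~ d * r**i + eps``.

    Constrained to d in [0,1], r in (0,1), eps >= 0. Needs at least three
    defined positions. An all-zero spectrum returns d_hat = 0 with the
    decay ratio flagged undefined.
    """
    mask = spectrum.defined5() & np.isfinite(spectrum.f5)
    xs = np.nonzero(mask)[0]
    ys = spectrum.f5[mask]
    if len(xs) < 3:
        raise ValueError("need >= 3 defined spectrum positions to fit")
    if np.all(ys == 0):
        return DecayFit(0.0, np.nan, 0.0, 0.0, len(xs), degenerate=True)

    def residuals(params):
        d, r, eps = params
        return d * r**xs + eps - ys

    tail = float(np.mean(ys[xs >= max(xs.max() - 3, len(xs) // 2)]))
    d0 = float(np.clip(ys[0] - tail, 1e-3, 1.0))
    r0 = 0.5
    eps0 = float(np.clip(tail, 0.0, 1.0))
    fit = least_squares(
        residuals,
        x0=[d0, r0, eps0],
        bounds=([0.0, 1e-6, 0.0], [1.0, 1.0 - 1e-6, 1.0]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    d, r, eps = fit.x
    return DecayFit(
        float(d), float(r), float(eps), float(2 * fit.cost), len(xs)
    )


def calls_to_tsv(calls: Sequence[ReadDamageCall], path: str | Path) -> None:
    rows = [
        (
            c.read_id,
            c.sample_id,
            c.taxon_id,
            c.call,
            ";".join(f"{p}:{k}" for p, k in c.evidence),
        )
        for c in calls
    ]
    pd.DataFrame(
        rows, columns=["read_id", "sample_id", "taxon_id", "call", "evidence"]
    ).to_csv(path, sep="\t", index=False)
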