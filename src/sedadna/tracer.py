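"""Drill-fluid tracer (PFMD) contamination assessment.

Perfluoromethyldecalin is infused into the drill fluid while coring;
measuring it at the core periphery and centre of each sampling depth
tells whether drill fluid — and hence modern DNA — can have reached the
material used for extraction. The module implements blank correction,
the 3x-SD detection limit with its lowest-standard fallback, the
stereoisomer calibration of nominal standard concentrations, and
per-sample contamination verdicts.

Concentrations are ng mL^-1 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

ISOMER_FRACTION = 0.88  # measurable stereoisomer share of bottle concentration
LOCATIONS = ("periphery", "centre", "drill_fluid")


class TracerError(ValueError):
    """Procedural error in tracer processing (missing blanks, replicates...)."""


@dataclass(frozen=True)
class TracerStandard:
    """One calibration standard level with replicate measurements."""

    nominal: float
    replicates: tuple[float, ...]


@dataclass(frozen=True)
class TracerRun:
    """One GC measurement batch: blanks, standards, core measurements.

    ``measurements`` holds (sample_id, location, value) triples;
    ``corrected`` guards against double blank-correction.
    """

    run_id: str
    site: str
    blanks: tuple[float, ...]
    standards: tuple[TracerStandard, ...]
    measurements: tuple[tuple[str, str, float], ...]
    corrected: bool = False

    def __post_init__(self):
        if len(self.blanks) < 2:
            raise TracerError("a run requires at least duplicate blanks")
        if any(b < 0 for b in self.blanks):
            raise TracerError("negative blank concentration")
        for _, location, value in self.measurements:
            if location not in LOCATIONS:
                raise TracerError(f"unknown measurement location {location!r}")
            if value < 0:
                raise TracerError("negative measurement")

    def to_rows(self) -> list[tuple]:
        rows = [
            (self.run_id, self.site, "blank", "", "", np.nan, b) for b in self.blanks
        ]
        for std in self.standards:
            rows.extend(
                (self.run_id, self.site, "standard", "", "", std.nominal, v)
                for v in std.replicates
            )
        rows.extend(
            (self.run_id, self.site, "sample", sid, loc, np.nan, v)
            for sid, loc, v in self.measurements
        )
        return rows


@dataclass(frozen=True)
class TracerVerdict:
    """Per-sample contamination call against the run detection limit."""

    sample_id: str
    corrected_periphery: float | None   # None == measurement missing
    corrected_centre: float | None
    detection_limit: float
    periphery_below_limit: bool
    centre_below_limit: bool
    flags: frozenset[str]
    note: str = ""


def blank_correct(run: TracerRun) -> TracerRun:
    """Subtract the run's mean blank from every measurement, floored at 0.

    Applying the correction twice would silently shift concentrations, so
    a second call on an already-corrected run raises.
    """
    if run.corrected:
        raise TracerError(f"run {run.run_id} is already blank-corrected")
    if not run.blanks:
        raise TracerError("no blanks in run")
    mean_blank = float(np.mean(run.blanks))
    corrected = tuple(
        (sid, loc, max(0.0, value - mean_blank)) for sid, loc, value in run.measurements
    )
    return replace(run, measurements=corrected, corrected=True)


def detection_limit(run: TracerRun, ddof: int = 1) -> float:
    """3x the SD of the run's blanks; lowest-standard fallback when 0.

    Sample SD (``ddof=1``) by default. When every blank reads identically
    (typically all zero) the blank SD carries no information and the SD of
    the lowest standard's replicates is used instead; that fallback needs
    at least two replicates.
    """
    if not run.blanks:
        raise TracerError("no blanks in run")
    sd = float(np.std(run.blanks, ddof=ddof))
    if sd > 0:
        return 3.0 * sd
    lowest = min(run.standards, key=lambda s: s.nominal, default=None)
    if lowest is None:
        raise TracerError("blank SD is 0 and run has no standards for fallback")
    if len(lowest.replicates) < 2:
        raise TracerError("lowest standard needs >= 2 replicates for the fallback")
    return 3.0 * float(np.std(lowest.replicates, ddof=ddof))


def isomer_calibrate(nominal_level: float, fraction: float = ISOMER_FRACTION) -> float:
    """Effective standard concentration: measurable isomer share of the
    nominal bottle concentration."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    return nominal_level * fraction


def standard_curve(
    run: TracerRun, fraction: float = ISOMER_FRACTION
) -> tuple[float, float]:
    """Linear calibration (slope, intercept) of measured standard values
    against isomer-calibrated nominal concentrations."""
    xs, ys = [], []
    for std in run.standards:
        effective = isomer_calibrate(std.nominal, fraction)
        for v in std.replicates:
            xs.append(effective)
            ys.append(v)
    if len(set(xs)) < 2:
        raise TracerError("need >= 2 distinct standard levels for a curve")
    fit = stats.linregress(xs, ys)
    return float(fit.slope), float(fit.intercept)


def assess_contamination(
    run: TracerRun, ddof: int = 1
) -> tuple[list[TracerVerdict], dict[str, int]]:
    """Per-sample verdicts plus a run-level summary.

    Requires a blank-corrected run. Values below the detection limit are
    rejected (reported below-limit); surviving values set the flags.
    """
    if not run.corrected:
        raise TracerError("assess_contamination requires a blank-corrected run")
    limit = detection_limit(run, ddof=ddof)
    per_sample: dict[str, dict[str, float]] = {}
    for sid, loc, value in run.measurements:
        if loc == "drill_fluid":
            continue
        per_sample.setdefault(sid, {})[loc] = value
    verdicts = []
    summary = {"clean": 0, "periphery_detected": 0, "centre_detected": 0}
    for sid in sorted(per_sample):
        values = per_sample[sid]
        peri = values.get("periphery")
        cent = values.get("centre")
        note = ""
        if peri is None or cent is None:
            missing = [l for l in ("periphery", "centre") if l not in values]
            note = f"missing measurement: {','.join(missing)}"
        flags = set()
        peri_below = peri is None or peri < limit
        cent_below = cent is None or cent < limit
        if cent is not None and not cent_below:
            flags.add("centre_detected")
            note = (note + "; " if note else "") + (
                "tracer at core centre: interpret sedaDNA with caution"
            )
        if peri is not None and not peri_below:
            flags.add("periphery_detected")
        if not flags:
            flags.add("clean")
        for f in flags:
            summary[f] += 1
        verdicts.append(
            TracerVerdict(
                sample_id=sid,
                corrected_periphery=peri,
                corrected_centre=cent,
                detection_limit=limit,
                periphery_below_limit=peri_below,
                centre_below_limit=cent_below,
                flags=frozenset(flags),
                note=note,
            )
        )
    return verdicts, summary


# ---------------------------------------------------------------------------
# TSV round trip
# ---------------------------------------------------------------------------

_COLUMNS = ["run_id", "site", "kind", "sample_id", "location", "nominal_level", "value"]


def runs_to_tsv(runs: Iterable[TracerRun], path: str | Path) -> None:
    rows = []
    for run in runs:
        rows.extend(run.to_rows())
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, sep="\t", index=False)


def runs_from_tsv(path: str | Path) -> list[TracerRun]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])
    runs = []
    for (run_id, site), grp in df.groupby(["run_id", "site"], sort=False):
        blanks = tuple(grp.loc[grp["kind"] == "blank", "value"].astype(float))
        standards = tuple(
            TracerStandard(float(nominal), tuple(sub["value"].astype(float)))
            for nominal, sub in grp[grp["kind"] == "standard"].groupby("nominal_level")
        )
        measurements = tuple(
            (str(r.sample_id), str(r.location), float(r.value))
            for r in grp[grp["kind"] == "sample"].itertuples(index=False)
        )
        runs.append(TracerRun(str(run_id), str(site), blanks, standards, measurements))
    return runs


def verdicts_to_tsv(verdicts: Sequence[TracerVerdict], path: str | Path) -> None:
    rows = [
        (
            v.sample_id,
            "" if v.corrected_periphery is None else v.corrected_periphery,
            "" if v.corrected_centre is None else v.corrected_centre,
            v.detection_limit,
            v.periphery_below_limit,
            v.centre_below_limit,
            ";".join(sorted(v.flags)),
            v.note,
        )
        for v in verdicts
    ]
    pd.DataFrame(
        rows,
        columns=[
            "sample_id", "corrected_periphery", "corrected_centre", "detection_limit",
            "periphery_below_limit", "centre_below_limit", "flags", "note",
        ],
    ).to_csv(path, sep="\t", index=False)
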