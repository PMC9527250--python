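"""Control-based contaminant removal from taxon profiles.

Any taxon observed in an extraction blank, air, or drill-fluid control
is treated as a putative laboratory/field contaminant. Two modes:

* ``remove_taxon`` (default, conservative) — zero the taxon everywhere
  in scope;
* ``subtract_counts`` — reduce each sample's count by the maximum count
  seen for that taxon across in-scope controls, floored at zero.

Scope is per-site by default (controls are collected per site); a global
scope pools all controls.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from .align import TaxonProfile

MODES = ("remove_taxon", "subtract_counts")
SCOPES = ("per_site", "global")


@dataclass
class SubtractionReport:
    """Audit trail: per-(sample, taxon) before/removed/after counts for
    every contaminant taxon, plus the control-derived contaminant list."""

    changes: pd.DataFrame      # sample_id, taxon_id, count_before, count_removed, count_after
    contaminants: pd.DataFrame  # scope_key, taxon_id, max_control_count, n_controls_detected

    def validate(self) -> None:
        df = self.changes
        if not (df["count_after"] == df["count_before"] - df["count_removed"]).all():
            raise AssertionError("subtraction report identity violated")
        if (df["count_after"] < 0).any():
            raise AssertionError("negative count after subtraction")

    def to_tsv(self, path: str | Path) -> None:
        self.changes.to_csv(path, sep="\t", index=False)

    def contaminants_to_tsv(self, path: str | Path) -> None:
        self.contaminants.to_csv(path, sep="\t", index=False)


def subtract_controls(
    samples: TaxonProfile,
    controls: TaxonProfile,
    mode: str = "remove_taxon",
    scope: str = "per_site",
    sites: Mapping[str, str] | None = None,
) -> tuple[TaxonProfile, SubtractionReport]:
    """Remove control-supported taxa from sample profiles.

    ``sites`` maps sample and control ids to a site label; required for
    per-site scope. Counts never increase and the operation is
    idempotent in both modes.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if scope not in SCOPES:
        raise ValueError(f"unknown scope {scope!r}")
    overlap = set(samples.samples) & set(controls.samples)
    if overlap:
        raise ValueError(f"ids present in both samples and controls: {sorted(overlap)}")
    if scope == "per_site":
        if sites is None:
            raise ValueError("per_site scope requires a sample→site mapping")
        missing = [
            s for s in list(samples.samples) + list(controls.samples) if s not in sites
        ]
        if missing:
            raise ValueError(f"no site for ids: {missing}")
        site_of = dict(sites)
    else:
        site_of = {s: "__all__" for s in list(samples.samples) + list(controls.samples)}

    counts = samples.counts.copy()
    change_rows = []
    contaminant_rows = []
    for site in sorted({site_of[s] for s in samples.samples}):
        site_samples = [s for s in samples.samples if site_of[s] == site]
        site_controls = [c for c in controls.samples if site_of[c] == site]
        if not site_controls:
            continue
        ctrl = controls.counts.loc[site_controls]
        ctrl_max = ctrl.max(axis=0)
        contaminant_taxa = [t for t in ctrl.columns if ctrl_max[t] > 0]
        for taxon in contaminant_taxa:
            contaminant_rows.append(
                (site, taxon, int(ctrl_max[taxon]), int((ctrl[taxon] > 0).sum()))
            )
            if taxon not in counts.columns:
                continue
            for sample in site_samples:
                before = int(counts.loc[sample, taxon])
                if mode == "remove_taxon":
                    removed = before
                else:
                    removed = min(before, int(ctrl_max[taxon]))
                if removed or before:
                    change_rows.append(
                        (sample, taxon, before, removed, before - removed)
                    )
                counts.loc[sample, taxon] = before - removed

    report = SubtractionReport(
        changes=pd.DataFrame(
            change_rows,
            columns=[
                "sample_id", "taxon_id", "count_before", "count_removed", "count_after",
            ],
        ),
        contaminants=pd.DataFrame(
            contaminant_rows,
            columns=["scope_key", "taxon_id", "max_control_count", "n_controls_detected"],
        ),
    )
    report.validate()
    out = TaxonProfile(
        counts, samples.unassigned.copy(), samples.unclassified, samples.rank
    )
    return out, report
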