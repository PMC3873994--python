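"""Cohort assembly: the site and site-year exclusion rules.

Three rules are applied in order, independently for each metric (SCU and
ECU cohorts differ because spring and autumn transitions fail on different
site-years):

1. compute the per-biome mean date across all site-years in a single pass,
   then exclude every site whose site-mean date deviates from its biome
   mean by more than 60 days (means are not recomputed after exclusions);
2. exclude site-years whose metric is absent (daily NEE missing or
   unretrievable during the transition period);
3. drop biome cells left with fewer than 10 site-years.

Every input site-year ends up exactly once: included, or in the exclusion
ledger with the rule that removed it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

RULE_SITE_DEVIATION = "site_deviation_gt_max"
RULE_MISSING_METRIC = "metric_unretrievable"
RULE_SMALL_BIOME = "biome_below_min_site_years"


@dataclass(frozen=True)
class SiteYearRecord:
    """One site-year's retrieved date for one metric (None = absent)."""

    site_id: str
    year: int
    biome: str
    value: Optional[float]


@dataclass
class CohortReport:
    """Included records plus the exclusion ledger for one metric."""

    metric: str
    included: list = field(default_factory=list)
    excluded: list = field(default_factory=list)  # (record, rule)

    @property
    def n_included(self) -> int:
        return len(self.included)

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)

    def counts_by_biome(self) -> dict:
        out: dict = {}
        for rec in self.included:
            out[rec.biome] = out.get(rec.biome, 0) + 1
        return out

    def ledger_rows(self) -> list[dict]:
        rows = [{"site_id": r.site_id, "year": r.year, "biome": r.biome,
                 "metric": self.metric, "status": "included", "rule": ""}
                for r in self.included]
        rows += [{"site_id": r.site_id, "year": r.year, "biome": r.biome,
                  "metric": self.metric, "status": "excluded", "rule": rule}
                 for r, rule in self.excluded]
        return rows


def filter_cohort(records: list[SiteYearRecord], metric: str = "scu",
                  min_site_years: int = 10,
                  max_deviation: float = 60.0) -> CohortReport:
    """Apply the three exclusion rules and return the accounting report."""
    report = CohortReport(metric=metric)
    if not records:
        return report

    # rule 1: biome means over ALL site-years with a value (single pass),
    # site means from each site's available values
    biome_values: dict = {}
    site_values: dict = {}
    for r in records:
        if r.value is not None:
            biome_values.setdefault(r.biome, []).append(r.value)
            site_values.setdefault((r.biome, r.site_id), []).append(r.value)
    biome_mean = {b: float(np.mean(v)) for b, v in biome_values.items()}
    bad_sites = {
        key for key, vals in site_values.items()
        if abs(float(np.mean(vals)) - biome_mean[key[0]]) > max_deviation
    }

    survivors = []
    for r in records:
        if (r.biome, r.site_id) in bad_sites:
            report.excluded.append((r, RULE_SITE_DEVIATION))
        elif r.value is None:
            report.excluded.append((r, RULE_MISSING_METRIC))
        else:
            survivors.append(r)

    # rule 3: biome cells below the minimum
    counts: dict = {}
    for r in survivors:
        counts[r.biome] = counts.get(r.biome, 0) + 1
    for r in survivors:
        if counts[r.biome] < min_site_years:
            report.excluded.append((r, RULE_SMALL_BIOME))
        else:
            report.included.append(r)
    return report
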