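"""Nearest-living-relative (NLR) trait reconstruction from fossil pollen.

Fossil spore/pollen species carry no direct trait measurements, but their
nearest living relatives do.  This module averages present-day trait
observations (plant height, leaf mass per area, phenology coded 0 =
deciduous / 1 = evergreen) at genus and family level, assigns each fossil
species the mean across its candidate NLR taxa, and aggregates
abundance-weighted community trait values per sample and time bin
(Paleocene P, event body B, recovery R, Eocene E), with coverage
reporting (the fraction of species with trait data).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TRAITS = ("height", "lma", "phenology")
TIME_BINS = ("P", "B", "R", "E")

__all__ = ["TRAITS", "TIME_BINS", "build_trait_lookup",
           "assign_species_traits", "reconstruct_sample",
           "reconstruct_series"]


def build_trait_lookup(trait_table: pd.DataFrame) -> dict:
    """Genus- and family-level unweighted trait means.

    ``trait_table`` needs columns (taxon, genus, family, trait, value);
    trait names are 'height' (m), 'lma' (g m-2) and 'phenology' (0/1 per
    observation).  Every observation carries the same weight, so the mean
    approximates the most common trait value within the taxon.  Returns
    ``{"genus": DataFrame, "family": DataFrame}`` indexed by taxon with
    one column per trait plus ``n_observations``.
    """
    required = {"genus", "family", "trait", "value"}
    missing = required - set(trait_table.columns)
    if missing:
        raise KeyError(f"trait table lacks columns {sorted(missing)}")
    df = trait_table.dropna(subset=["trait", "value"]).copy()
    if df.empty:
        logger.warning("empty trait table: lookup has no entries")
    bad_phen = df[(df["trait"] == "phenology")
                  & ~df["value"].between(0.0, 1.0)]
    if len(bad_phen):
        raise ValueError("phenology observations must lie in [0, 1]")
    lookup = {}
    for rank in ("genus", "family"):
        sub = df.dropna(subset=[rank])
        if sub.empty:
            lookup[rank] = pd.DataFrame(columns=[*TRAITS, "n_observations"])
            continue
        means = (sub.pivot_table(index=rank, columns="trait", values="value",
                                 aggfunc="mean"))
        counts = sub.groupby(rank)["value"].size().rename("n_observations")
        lookup[rank] = means.join(counts)
    return lookup


def _split_candidates(cell) -> list[str]:
    if isinstance(cell, (list, tuple)):
        return [str(c).strip() for c in cell if str(c).strip()]
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return []
    return [c.strip() for c in str(cell).split(";") if c.strip()]


def assign_species_traits(species_row, lookup: dict, level: str):
    """Trait triple for one fossil species, or None if no candidate NLR
    taxon at the requested level has data.

    With several plausible NLR candidates the species receives the plain
    mean across the candidate taxa that have data for each trait.
    """
    if level not in ("genus", "family"):
        raise ValueError("level must be 'genus' or 'family'")
    key = "nlr_genera" if level == "genus" else "nlr_families"
    candidates = _split_candidates(species_row.get(key))
    table = lookup[level]
    rows = [table.loc[c] for c in candidates if c in table.index]
    if not rows:
        return None
    sub = pd.DataFrame(rows)
    out = {t: float(sub[t].mean()) if t in sub and sub[t].notna().any()
           else np.nan for t in TRAITS}
    if all(np.isnan(v) for v in out.values()):
        return None
    return out


def reconstruct_sample(sample: pd.DataFrame, lookup: dict, level: str):
    """Abundance-weighted community trait means for one fossil sample.

    ``sample`` rows: (fossil_species, abundance, nlr_genera, nlr_families).
    Abundances are renormalised over the species that have trait data;
    coverage is the fraction of species (by count) with data at the
    level, with abundance-weighted coverage as a secondary diagnostic.
    """
    total_ab = sample["abundance"].sum()
    if not total_ab > 0:
        raise ValueError("sample abundances must sum to a positive total")
    assigned, weights = [], []
    for _, row in sample.iterrows():
        traits = assign_species_traits(row, lookup, level)
        if traits is not None:
            assigned.append(traits)
            weights.append(float(row["abundance"]))
    n_species = len(sample)
    coverage = len(assigned) / n_species
    cov_ab = sum(weights) / total_ab
    if not assigned:
        logger.warning("no species in sample has %s-level trait data", level)
        means = {t: np.nan for t in TRAITS}
        return means, coverage, cov_ab
    w = np.asarray(weights, dtype=float)
    means = {}
    for t in TRAITS:
        vals = np.array([a[t] for a in assigned], dtype=float)
        ok = ~np.isnan(vals)
        means[t] = float(np.average(vals[ok], weights=w[ok])) if ok.any() else np.nan
    return means, coverage, cov_ab


def reconstruct_series(samples: pd.DataFrame, lookup: dict) -> pd.DataFrame:
    """Per-site, per-bin community trait series at genus and family level.

    ``samples`` is a long table with columns (site, time_bin, sequence,
    fossil_species, abundance, nlr_genera, nlr_families); samples are
    ordered by ``sequence`` within a site.  Returns a tidy table (site,
    time_bin, sequence, level, trait, value, coverage,
    coverage_abundance) suitable for comparing relative change over time
    against modelled regional trait series.
    """
    out_rows = []
    for (site, tbin, seq), grp in samples.groupby(
            ["site", "time_bin", "sequence"], sort=False):
        for level in ("genus", "family"):
            means, cov, cov_ab = reconstruct_sample(grp, lookup, level)
            for t in TRAITS:
                out_rows.append({
                    "site": site, "time_bin": tbin, "sequence": seq,
                    "level": level, "trait": t, "value": means[t],
                    "coverage": cov, "coverage_abundance": cov_ab})
    df = pd.DataFrame(out_rows)
    bin_order = {b: i for i, b in enumerate(TIME_BINS)}
    df["bin_order"] = df["time_bin"].map(bin_order)
    return (df.sort_values(["site", "bin_order", "sequence", "level", "trait"])
            .drop(columns="bin_order").reset_index(drop=True))
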