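"""Record cleaning for museum/field body-size data.

Fixed pipeline order (logged, idempotent on its own output):

1. honor an optional provider ``exclude`` flag
2. drop invalid records (impossible or equal coordinates, missing date,
   coordinates, size, or species id)
3. reclassify life stage / sex vocabularies
4. harmonize species names through a synonym table
5. (covariates are attached between steps 4 and 5 by the pipeline)
6. drop records labelled juvenile
7. per species, retain records within k median absolute deviations (MADs,
   unscaled, inclusive band) of the adult median; below-band removals are
   counted as likely juveniles, above-band as outliers
8. drop species with fewer than ``n_min`` unique measurements of the metric
9. derive log10 sizes and the cube-root-mass / length ratio

Every removal is counted per rule in a :class:`CleaningReport` whose counts
reconcile exactly with the row-count delta.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats_io import LIFE_STAGES, SEXES, SynonymTable

logger = logging.getLogger(__name__)

RULES = [
    "provider_exclude", "impossible_coordinates", "lat_equals_lon",
    "missing_date", "missing_coordinates", "missing_size", "missing_species",
    "unresolved_name", "juvenile_stage", "below_mad_band", "above_mad_band",
    "no_adult_reference", "below_min_count",
]


@dataclass
class CleaningReport:
    """Counts removed per rule, plus species retained."""

    removed: dict[str, int] = field(default_factory=dict)
    n_input: int = 0
    n_output: int = 0
    species_retained: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def add(self, rule: str, n: int) -> None:
        if n:
            self.removed[rule] = self.removed.get(rule, 0) + int(n)

    @property
    def total_removed(self) -> int:
        return sum(self.removed.values())

    def reconciles(self) -> bool:
        return self.n_input - self.n_output == self.total_removed

    def merge(self, other: "CleaningReport") -> None:
        for k, v in other.removed.items():
            self.add(k, v)
        self.notes.extend(other.notes)

    def to_dict(self) -> dict:
        return {"n_input": self.n_input, "n_output": self.n_output,
                "removed": {k: self.removed[k] for k in sorted(self.removed)},
                "species_retained": sorted(self.species_retained),
                "notes": list(self.notes)}


def filter_invalid_records(table: pd.DataFrame
                           ) -> tuple[pd.DataFrame, CleaningReport]:
    """Drop records that cannot enter the pipeline at all."""
    rep = CleaningReport(n_input=len(table))
    t = table

    if "exclude" in t.columns:
        drop = t["exclude"].fillna(False).astype(bool)
        rep.add("provider_exclude", drop.sum())
        t = t[~drop]

    lat, lon = t["lat"], t["lon"]
    checks = [
        ("missing_species", t["species_id"].isna() | (t["species_id"].astype("string").str.strip() == "")),
        ("missing_coordinates", lat.isna() | lon.isna()),
        ("impossible_coordinates", (lat.abs() > 90) | (lon.abs() > 180)),
        ("lat_equals_lon", lat == lon),
        ("missing_date", t["year"].isna() | t["month"].isna()),
        ("missing_size", t["mass"].isna() & t["length"].isna()),
    ]
    keep = pd.Series(True, index=t.index)
    for rule, bad in checks:
        bad = bad.fillna(False) & keep
        rep.add(rule, bad.sum())
        keep &= ~bad
    t = t[keep].copy()
    rep.n_output = len(t)
    if rep.n_output == 0:
        warnings.warn("no records survived the validity filter")
    return t, rep


def reclassify_vocab(table: pd.DataFrame, stage_map: dict[str, str],
                     sex_map: dict[str, str]) -> pd.DataFrame:
    """Map raw life-stage/sex strings onto the closed vocabularies.

    Unmapped values become 'unknown'. Idempotent: canonical values map to
    themselves.
    """
    t = table.copy()

    def apply(col, mapping, vocab):
        raw = t[col].astype("string").fillna("unknown")
        full = {**{v: v for v in vocab}, **mapping}
        out = raw.map(lambda s: full.get(s, "unknown"))
        bad = set(out) - vocab
        assert not bad, f"map produced out-of-vocabulary values {bad}"
        t[col] = out.astype("string")

    apply("life_stage", stage_map, LIFE_STAGES)
    apply("sex", sex_map, SEXES)
    return t


def harmonize_names(table: pd.DataFrame, synonyms: SynonymTable
                    ) -> tuple[pd.DataFrame, CleaningReport]:
    """Replace species ids by canonical binomials; drop unresolvable names."""
    rep = CleaningReport(n_input=len(table))
    t = table.copy()
    resolved = t["species_id"].map(lambda s: synonyms.resolve(str(s)))
    bad = resolved.isna()
    if bad.any():
        names = sorted(t.loc[bad, "species_id"].unique())
        rep.notes.append(f"unresolved names excluded: {names}")
        logger.warning("unresolved species names: %s", names)
    rep.add("unresolved_name", bad.sum())
    t = t[~bad].copy()
    t["species_id"] = resolved[~bad].astype("string")
    rep.n_output = len(t)
    return t, rep


def assign_sites(table: pd.DataFrame, precision_decimals: int = 4
                 ) -> pd.DataFrame:
    """Integer site id: records share a site iff rounded (lat, lon) coincide."""
    t = table.copy()
    key = list(zip(t["lat"].round(precision_decimals),
                   t["lon"].round(precision_decimals)))
    codes, _ = pd.factorize(pd.Series(key), sort=True)
    t["site"] = codes
    return t


def drop_juveniles(table: pd.DataFrame) -> tuple[pd.DataFrame, CleaningReport]:
    rep = CleaningReport(n_input=len(table))
    juv = table["life_stage"] == "juvenile"
    rep.add("juvenile_stage", juv.sum())
    out = table[~juv].copy()
    rep.n_output = len(out)
    return out, rep


def mad_filter(table: pd.DataFrame, metric: str, k: float = 5.0
               ) -> tuple[pd.DataFrame, CleaningReport]:
    """Retain records within k MADs of the per-species adult median.

    The median and MAD (median absolute deviation, unscaled — no 1.4826
    consistency constant) are computed on adult records only, on the raw
    metric. The band is inclusive. Below-band removals count as likely
    juveniles, above-band as outliers. Species with MAD = 0 are retained in
    full with a warning; unknown-stage records of a species with no adult
    reference are removed. Records missing the metric pass through untouched.
    """
    rep = CleaningReport(n_input=len(table))
    t = table
    has = t[metric].notna()
    keep = pd.Series(True, index=t.index)

    for sp, g in t[has].groupby("species_id", sort=True):
        adults = g.loc[g["life_stage"] == "adult", metric].astype(float)
        if len(adults) == 0:
            rep.add("no_adult_reference", len(g))
            keep.loc[g.index] = False
            continue
        med = float(adults.median())
        mad = float((adults - med).abs().median())
        if mad == 0.0:
            warnings.warn(f"{sp}: adult MAD of {metric} is 0; "
                          "all records retained")
            rep.notes.append(f"{sp}: MAD=0, retained in full")
            continue
        x = g[metric].astype(float)
        below = x < med - k * mad
        above = x > med + k * mad
        rep.add("below_mad_band", below.sum())
        rep.add("above_mad_band", above.sum())
        keep.loc[g.index[below | above]] = False

    out = t[keep].copy()
    rep.n_output = len(out)
    return out, rep


def min_count_filter(table: pd.DataFrame, metric: str, n_min: int = 100
                     ) -> tuple[pd.DataFrame, CleaningReport]:
    """Drop species with fewer than n_min unique measurements of the metric.

    'Unique' = distinct (value, year, month, day, lat, lon) tuples, guarding
    against exact duplicate ingestion.
    """
    rep = CleaningReport(n_input=len(table))
    has = table[metric].notna()
    uniq = (table[has]
            .drop_duplicates(subset=[ "species_id", metric, "year", "month",
                                      "day", "lat", "lon"])
            .groupby("species_id", sort=False).size())
    good = set(uniq[uniq >= n_min].index)
    # rows missing the metric leave this metric's dataset too
    drop = ~table["species_id"].isin(good) | ~has
    rep.add("below_min_count", drop.sum())
    out = table[~drop].copy()
    rep.n_output = len(out)
    rep.species_retained = sorted(good)
    return out, rep


def derive_size_metrics(table: pd.DataFrame) -> pd.DataFrame:
    """log10 mass/length and the cube-root-mass / length ratio.

    The ratio mass^(1/3)/length tracks volume-to-surface-area; lower values
    mean relatively more surface for heat exchange. Non-positive sizes are
    flagged invalid (invalid_size=True) and their derived fields left missing.
    """
    t = table.copy()
    mass = t["mass"].astype(float)
    length = t["length"].astype(float)
    bad = ((mass <= 0) & mass.notna()) | ((length <= 0) & length.notna())
    if bad.any():
        logger.warning("%d records with non-positive size flagged invalid",
                       int(bad.sum()))
    t["invalid_size"] = bad
    with np.errstate(invalid="ignore", divide="ignore"):
        t["log10_mass"] = np.where(mass > 0, np.log10(mass), np.nan)
        t["log10_length"] = np.where(length > 0, np.log10(length), np.nan)
        t["mass_length_ratio"] = np.where(
            (mass > 0) & (length > 0), np.cbrt(mass) / length, np.nan)
    return t


def clean_pre_covariates(table: pd.DataFrame, synonyms: SynonymTable,
                         stage_map: dict[str, str], sex_map: dict[str, str],
                         site_decimals: int = 4
                         ) -> tuple[pd.DataFrame, CleaningReport]:
    """Steps 1-4 plus site assignment (before covariate attachment)."""
    t, rep = filter_invalid_records(table)
    t = reclassify_vocab(t, stage_map, sex_map)
    t, rep2 = harmonize_names(t, synonyms)
    rep.merge(rep2)
    t = assign_sites(t, site_decimals)
    rep.n_output = len(t)
    return t, rep


def clean_post_covariates(table: pd.DataFrame, metric: str, k: float = 5.0,
                          n_min: int = 100
                          ) -> tuple[pd.DataFrame, CleaningReport]:
    """Steps 6-9 for one metric dataset (after covariate attachment)."""
    t, rep = drop_juveniles(table)
    t, rep2 = mad_filter(t, metric, k)
    t, rep3 = min_count_filter(t, metric, n_min)
    rep.merge(rep2)
    rep.merge(rep3)
    rep.species_retained = rep3.species_retained
    t = derive_size_metrics(t)
    rep.n_output = len(t)
    rep.n_input = len(table)
    assert rep.reconciles(), "cleaning report does not reconcile"
    return t, rep
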