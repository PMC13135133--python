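"""Data model and I/O for point-intercept vegetation surveys.

A plot is sampled at ``n_pinpoints`` point-intercept positions (300 in the
standard protocol: two parallel 30 m lines read every 20 cm, flattened into a
single 0-based index space).  A species *occupies* a pinpoint when an
individual contacts it; several species may touch the same pinpoint.  The
tables exchanged on disk are UTF-8 TSV with a header row:

* survey: ``plot_id, pinpoint_id, species_id`` — one row per presence record;
* plot manifest: ``plot_id, n_pinpoints``;
* environment: one row per plot, keyed by ``plot_id``;
* traits: one row per species, keyed by ``species_id``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "PlotSurvey",
    "SurveyCollection",
    "read_survey",
    "write_survey",
    "read_plot_manifest",
    "read_environment_table",
    "read_trait_table",
    "cooccurring_pairs",
]

SURVEY_COLUMNS = ("plot_id", "pinpoint_id", "species_id")

ENVIRONMENT_COLUMNS = (
    "pH",
    "N_pct",
    "CN_ratio",
    "organic_matter",
    "GDD",
    "FDD",
    "ETP",
    "T_mean",
    "T_min_coldest",
    "precipitation",
)

TRAIT_COLUMNS = ("SLA", "LDMC", "leaf_area", "vegetative_height", "seed_mass")
CSR_COLUMNS = ("C", "S", "R")


class SurveyFormatError(ValueError):
    """A survey table misses required columns."""


class SurveyValidationError(ValueError):
    """A survey table violates the data-model invariants."""


@dataclass(frozen=True)
class PlotSurvey:
    """Occupancy of one plot: which pinpoints each species touches.

    Attributes
    ----------
    plot_id:
        Plot identifier, unique within a collection.
    n_pinpoints:
        Number of point-intercept positions (``N_s``); indices live in
        ``[0, n_pinpoints)``.
    occupancy:
        Mapping ``species_id -> frozenset`` of occupied pinpoint indices.
    """

    plot_id: str
    n_pinpoints: int
    occupancy: Mapping[str, frozenset]

    def __post_init__(self) -> None:
        if self.n_pinpoints <= 0:
            raise SurveyValidationError(
                f"plot {self.plot_id!r}: n_pinpoints must be positive"
            )
        for sp, points in self.occupancy.items():
            if not points:
                raise SurveyValidationError(
                    f"plot {self.plot_id!r}: species {sp!r} has empty occupancy"
                )
            lo, hi = min(points), max(points)
            if lo < 0 or hi >= self.n_pinpoints:
                raise SurveyValidationError(
                    f"plot {self.plot_id!r}: pinpoint index outside "
                    f"[0, {self.n_pinpoints}) for species {sp!r}"
                )

    @property
    def species(self) -> tuple:
        return tuple(sorted(self.occupancy))

    def count(self, species_id: str) -> int:
        """Occupied-pinpoint count ``n_is`` (0 when absent)."""
        pts = self.occupancy.get(species_id)
        return len(pts) if pts is not None else 0

    def colocation(self, species_i: str, species_j: str) -> int:
        """Number of pinpoints touched by both species (``n_ijs``)."""
        a = self.occupancy.get(species_i)
        b = self.occupancy.get(species_j)
        if a is None or b is None:
            return 0
        return len(a & b)

    @property
    def n_presence_records(self) -> int:
        """Total distinct (pinpoint, species) contacts, Σ_i n_is."""
        return sum(len(p) for p in self.occupancy.values())


@dataclass
class SurveyCollection:
    """A set of plots plus the global species catalogue."""

    plots: list = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.plot_id for p in self.plots]
        if len(set(ids)) != len(ids):
            raise SurveyValidationError("duplicate plot_id in collection")

    @property
    def plot_ids(self) -> list:
        return [p.plot_id for p in self.plots]

    @property
    def species_index(self) -> list:
        seen = set()
        for p in self.plots:
            seen.update(p.occupancy)
        return sorted(seen)

    def plot(self, plot_id: str) -> PlotSurvey:
        for p in self.plots:
            if p.plot_id == plot_id:
                return p
        raise KeyError(plot_id)

    def abundance_matrix(self) -> pd.DataFrame:
        """Plot × species table of occupied-pinpoint counts ``n_is``."""
        species = self.species_index
        data = {
            p.plot_id: [p.count(s) for s in species] for p in self.plots
        }
        return pd.DataFrame(data, index=species).T

    def n_individuals(self) -> pd.Series:
        """Per-plot pinpoint-contact totals (the 'individuals' covariate)."""
        return pd.Series(
            {p.plot_id: p.n_presence_records for p in self.plots},
            name="n_individuals",
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (p.plot_id, pt, sp)
            for p in self.plots
            for sp in sorted(p.occupancy)
            for pt in sorted(p.occupancy[sp])
        ]
        return pd.DataFrame(rows, columns=list(SURVEY_COLUMNS))


def _collection_from_frame(
    df: pd.DataFrame, manifest: Mapping[str, int] | None
) -> SurveyCollection:
    missing = set(SURVEY_COLUMNS) - set(df.columns)
    if missing:
        raise SurveyFormatError(f"survey table missing columns: {sorted(missing)}")
    df = df.loc[:, list(SURVEY_COLUMNS)].drop_duplicates()
    plots = []
    for plot_id, sub in df.groupby("plot_id", sort=True):
        pinpoints = sub["pinpoint_id"].to_numpy(dtype=int)
        if manifest is not None:
            if str(plot_id) not in manifest:
                raise SurveyValidationError(f"plot {plot_id!r} absent from manifest")
            n_pin = int(manifest[str(plot_id)])
            if pinpoints.max() >= n_pin or pinpoints.min() < 0:
                raise SurveyValidationError(
                    f"plot {plot_id!r}: pinpoint_id outside manifest range [0, {n_pin})"
                )
        else:
            n_pin = int(pinpoints.max()) + 1
        occ = {
            str(sp): frozenset(int(x) for x in grp["pinpoint_id"])
            for sp, grp in sub.groupby("species_id", sort=True)
        }
        plots.append(PlotSurvey(str(plot_id), n_pin, occ))
    return SurveyCollection(plots)


def read_survey(path, manifest=None) -> SurveyCollection:
    """Read a long-format survey TSV into a :class:`SurveyCollection`.

    Parameters
    ----------
    path:
        TSV with columns ``plot_id, pinpoint_id, species_id``; duplicated
        presence rows are collapsed (presence is binary per pinpoint).
    manifest:
        Either a path to a plot-manifest TSV (``plot_id, n_pinpoints``), a
        mapping ``plot_id -> n_pinpoints``, or None, in which case each plot's
        pinpoint count is inferred as ``max(pinpoint_id) + 1``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(SURVEY_COLUMNS) - set(df.columns)
    if missing:
        raise SurveyFormatError(f"survey table missing columns: {sorted(missing)}")
    if df.empty:
        return SurveyCollection([])
    df["pinpoint_id"] = df["pinpoint_id"].astype(int)
    if isinstance(manifest, (str, Path)):
        manifest = read_plot_manifest(manifest)
    return _collection_from_frame(df, manifest)


def write_survey(collection: SurveyCollection, path) -> None:
    """Write the collapsed presence records back to TSV (round-trip safe)."""
    collection.to_frame().to_csv(path, sep="\t", index=False)


def read_plot_manifest(path) -> dict:
    df = pd.read_csv(path, sep="\t", dtype={"plot_id": str})
    if not {"plot_id", "n_pinpoints"} <= set(df.columns):
        raise SurveyFormatError("plot manifest needs columns plot_id, n_pinpoints")
    return dict(zip(df["plot_id"], df["n_pinpoints"].astype(int)))


def read_environment_table(path) -> pd.DataFrame:
    """Plot-level abiotic table, indexed by plot_id; missing values stay NaN."""
    df = pd.read_csv(path, sep="\t", dtype={"plot_id": str}).set_index("plot_id")
    if df.index.has_duplicates:
        raise SurveyValidationError("environment table has duplicate plot_id rows")
    if "N_pct" in df.columns and (df["N_pct"].dropna() < 0).any():
        raise SurveyValidationError("N_pct must be non-negative")
    return df


def read_trait_table(path) -> pd.DataFrame:
    """Species × trait table; optional CSR columns must sum to 1 per row."""
    df = pd.read_csv(path, sep="\t", dtype={"species_id": str}).set_index("species_id")
    present = [c for c in TRAIT_COLUMNS if c in df.columns]
    for c in present:
        vals = df[c].dropna()
        if (vals <= 0).any():
            raise SurveyValidationError(f"trait {c} must be strictly positive")
    if set(CSR_COLUMNS) <= set(df.columns):
        csr = df[list(CSR_COLUMNS)].dropna()
        bad = (csr.sum(axis=1) - 1.0).abs() > 1e-9
        if bad.any():
            raise SurveyValidationError("CSR coordinates must sum to 1")
    return df


def cooccurring_pairs(collection: SurveyCollection) -> list:
    """Unordered species pairs sharing at least one plot.

    Returns ``[(species_i, species_j, [plot_ids...]), ...]`` with
    ``species_i < species_j``; co-occurrence means both species are present
    (n > 0) in the plot, regardless of pinpoint overlap.
    """
    shared: dict = {}
    for p in collection.plots:
        for a, b in itertools.combinations(sorted(p.occupancy), 2):
            shared.setdefault((a, b), []).append(p.plot_id)
    return [(a, b, plots) for (a, b), plots in sorted(shared.items())]
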