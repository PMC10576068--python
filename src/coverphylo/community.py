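"""Plot-level biomass data: ingestion, validation, and dissimilarity inputs.

The experimental unit is the plot (site x year x block x treatment); quadrat
samples are summed to the plot level to avoid pseudoreplication.  Taxon roles
split the table into weeds, cover crops, and unknown (unidentified) species:
unknowns stay in biomass totals and community dissimilarities but are
excluded from every phylogenetic computation.  Winter and summer experiments
are analyzed separately and are never pooled by any operation here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SchemaError",
    "CommunityTable",
    "read_biomass_table",
    "partition_roles",
    "log1p_matrix",
    "bray_curtis",
    "write_matrix",
]

REQUIRED_COLUMNS = (
    "site",
    "year",
    "block",
    "plot",
    "treatment",
    "taxon",
    "role",
    "biomass",
)
OPTIONAL_COLUMNS = ("quadrat", "units", "experiment")
ROLES = ("weed", "cover_crop", "unknown")
CONTROL = "control"

#: biomass unit -> factor converting to kg per hectare
#: g per 0.5 m^2 (two pooled 0.25 m^2 quadrats) scales by 10000/500 = 20
UNIT_FACTORS = {"kg_ha": 1.0, "g_per_0.5m2": 20.0}


class SchemaError(ValueError):
    """Input table violates the biomass-table schema."""


@dataclass(frozen=True)
class CommunityTable:
    """Validated plot-level biomass records with design metadata.

    ``data`` has one row per (plot, taxon) with columns
    site, year, block, plot, treatment, taxon, role, biomass (kg/ha).
    """

    data: pd.DataFrame

    def __post_init__(self):
        _validate(self.data)

    # -- views ----------------------------------------------------------

    def plots(self) -> pd.DataFrame:
        """One row per plot: design metadata lookup."""
        cols = ["site", "year", "block", "plot", "treatment"]
        return (
            self.data[cols].drop_duplicates().set_index("plot").sort_index()
        )

    def weeds(self) -> pd.DataFrame:
        return self.data[self.data["role"] == "weed"].copy()

    def covers(self) -> pd.DataFrame:
        return self.data[self.data["role"] == "cover_crop"].copy()

    def unknown_taxa(self) -> list[str]:
        return sorted(self.data.loc[self.data["role"] == "unknown", "taxon"].unique())

    def weed_like(self) -> pd.DataFrame:
        """Weed plus unknown records: everything that is not a cover crop.

        Unknown species are weeds with biomass; they only drop out of
        phylogenetic steps.
        """
        return self.data[self.data["role"].isin(["weed", "unknown"])].copy()

    def treatments(self) -> list[str]:
        return sorted(self.data["treatment"].unique())

    def cover_taxa_by_plot(self) -> dict[str, list[tuple[str, float]]]:
        """Per cover-crop plot: the (taxon, biomass) of its cover records."""
        out: dict[str, list[tuple[str, float]]] = {}
        for plot, grp in self.covers().groupby("plot"):
            out[plot] = list(zip(grp["taxon"], grp["biomass"]))
        return out

    def subset_plots(self, plot_ids) -> "CommunityTable":
        keep = self.data["plot"].isin(set(plot_ids))
        return CommunityTable(self.data[keep].reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.data)


def _validate(df: pd.DataFrame) -> None:
    problems = []
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    neg = df.index[df["biomass"] < 0].tolist()
    if neg:
        problems.append(f"negative biomass at row(s) {neg}")
    bad_role = sorted(set(df["role"]) - set(ROLES))
    if bad_role:
        problems.append(f"unknown role value(s) {bad_role}; expected {ROLES}")
    dup = df.duplicated(subset=["plot", "taxon"])
    if dup.any():
        pairs = df.loc[dup, ["plot", "taxon"]].drop_duplicates()
        problems.append(
            "duplicate (plot, taxon) after aggregation: "
            + ", ".join(f"({p}, {t})" for p, t in pairs.itertuples(index=False))
        )
    # a plot id must carry a single design assignment
    meta = df[["plot", "site", "year", "block", "treatment"]].drop_duplicates()
    dup_plot = meta["plot"][meta["plot"].duplicated()].tolist()
    if dup_plot:
        problems.append(f"plot(s) with conflicting design metadata: {dup_plot}")
    # randomized complete block: at most one plot per treatment per block
    multi = (
        meta.groupby(["site", "year", "block", "treatment"])["plot"]
        .nunique()
        .reset_index(name="n")
    )
    clashes = multi[multi["n"] > 1]
    if len(clashes):
        problems.append(
            "more than one plot for the same (site, year, block, treatment): "
            + ", ".join(
                f"({r.site}, {r.year}, {r.block}, {r.treatment})"
                for r in clashes.itertuples()
            )
        )
    if problems:
        raise SchemaError("; ".join(problems))


def read_biomass_table(path, sep: str | None = None) -> CommunityTable:
    """Read a delimited biomass table and aggregate it to the plot level.

    Comma is the default delimiter, tab is accepted (``sep=None`` sniffs).
    Quadrat-level rows are summed per (plot, taxon); a ``units`` column
    triggers conversion to kg/ha (``g_per_0.5m2`` scales by 20).  Schema
    violations are collected and reported together.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    df["biomass"] = pd.to_numeric(df["biomass"], errors="raise")
    neg = df.index[df["biomass"] < 0].tolist()
    if neg:
        raise SchemaError(f"negative biomass at row(s) {neg}")
    if "units" in df.columns:
        units = df["units"].fillna("kg_ha")
        bad = sorted(set(units) - set(UNIT_FACTORS))
        if bad:
            raise SchemaError(
                f"unrecognized units {bad}; expected {sorted(UNIT_FACTORS)}"
            )
        df["biomass"] = df["biomass"] * units.map(UNIT_FACTORS)
    for col in ("site", "year", "block", "plot", "treatment", "taxon", "role"):
        df[col] = df[col].astype(str).str.strip()
    # sum quadrats (and any other replicate rows) to the plot level
    keys = ["site", "year", "block", "plot", "treatment", "taxon", "role"]
    agg = df.groupby(keys, as_index=False, sort=True)["biomass"].sum()
    return CommunityTable(agg.reset_index(drop=True))


def partition_roles(
    table: CommunityTable,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Split records into (weeds, cover crops, unknown-taxon list).

    Unknown species are excluded from phylogenetic computations but retain
    their biomass in community totals (callers use ``weed_like`` for
    totals).  Cover-crop taxa recorded with role ``weed`` in control plots
    are volunteers: kept as weeds, flagged in the log.
    """
    weeds = table.weeds()
    covers = table.covers()
    unknown = table.unknown_taxa()
    if unknown:
        logger.info(
            "excluding %d unknown taxa from phylogenetic computations: %s",
            len(unknown),
            ", ".join(unknown),
        )
    cover_taxa = set(covers["taxon"])
    volunteers = weeds[
        weeds["taxon"].isin(cover_taxa) & (weeds["treatment"] == CONTROL)
    ]
    for row in volunteers.itertuples():
        logger.warning(
            "volunteer cover-crop taxon %r recorded as weed in control plot %s",
            row.taxon,
            row.plot,
        )
    return weeds, covers, unknown


def log1p_matrix(weeds: pd.DataFrame) -> pd.DataFrame:
    """Plot x taxon matrix of ln(1 + biomass).

    Plots whose weed biomass is entirely zero keep an all-zero row.
    """
    wide = weeds.pivot_table(
        index="plot", columns="taxon", values="biomass", aggfunc="sum", fill_value=0.0
    )
    return np.log1p(wide)


def bray_curtis(matrix: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis dissimilarity between plot rows.

    ``BC(x, y) = sum|x - y| / sum(x + y)``.  A pair of all-zero plots is
    defined as 0 (identical emptiness, logged); one empty plot against a
    non-empty one gives 1.  The matrix must be total for PERMANOVA.
    """
    X = np.asarray(matrix, dtype=float)
    if (X < 0).any():
        raise ValueError("Bray-Curtis requires nonnegative abundances")
    num = np.abs(X[:, None, :] - X[None, :, :]).sum(axis=2)
    den = (X[:, None, :] + X[None, :, :]).sum(axis=2)
    empty_pair = den == 0
    if empty_pair.sum() > len(X):  # off-diagonal empty pairs exist
        logger.warning(
            "Bray-Curtis: %d plot pair(s) are both empty; dissimilarity set to 0",
            int((empty_pair.sum() - len(X)) // 2),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        bc = np.where(empty_pair, 0.0, num / np.where(den == 0, 1.0, den))
    np.fill_diagonal(bc, 0.0)
    return pd.DataFrame(bc, index=matrix.index, columns=matrix.index)


def write_matrix(matrix: pd.DataFrame, path, sep: str = ",") -> None:
    """Write a labeled matrix (plot x taxon or plot x plot) as delimited text."""
    matrix.to_csv(path, sep=sep)
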