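"""Abundance-weighted interspecific mean pairwise distance and its
relativized cover-crop form.

Interspecific MPD of a community with relative abundances ``p_i`` on a
patristic matrix ``d_ij`` is

    MPD = sum_{i != j} p_i p_j d_ij / sum_{i != j} p_i p_j ,

the biomass-weighted mean patristic distance over pairs of *distinct* taxa
(conspecific i = j pairs are excluded).  It is invariant to rescaling all
abundances and, on constant-distance communities, to species richness.

The relativized statistic asks whether a cover crop is more or less related
to its weed community than expected from the resident weeds.  With the
cover taxa (and their measured biomass) added to a weed community,

    dMPD(community)   = MPD(cover + weeds) - MPD(weeds)
    MPD_relativized   = dMPD(weeds in cover plot) - dMPD(weeds in control)

Positive values mean the surviving weeds are phylogenetically *over-
dispersed* relative to the cover crop (related weeds were suppressed);
negative values mean clustering around the cover crop.  Subtracting the
control term removes the baseline distance between the chosen cover species
and the resident weed flora of that location.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from coverphylo.community import CONTROL, CommunityTable
from coverphylo.tree import PatristicMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "MPDResult",
    "RelativizedMPDResult",
    "interspecific_mpd",
    "delta_inter_mpd",
    "relativized_inter_mpd",
    "mpd_by_plot",
    "relativize_by_pairing",
]


@dataclass(frozen=True)
class MPDResult:
    value: float
    n_taxa: int
    plot: str | None = None
    defined: bool = True
    reason: str | None = None


@dataclass(frozen=True)
class RelativizedMPDResult:
    cover_plot: str
    control_plot: str
    mpd_weeds_cover: float
    mpd_weeds_control: float
    delta_cover: float
    delta_control: float
    relativized: float
    cover_taxa: tuple[str, ...]
    cover_weights: tuple[float, ...]
    defined: bool = True
    reason: str | None = None


def _positive_weights(
    abundances: Mapping[str, float], D: PatristicMatrix
) -> tuple[list[str], np.ndarray]:
    taxa, w = [], []
    for taxon, biomass in abundances.items():
        if biomass < 0:
            raise ValueError(f"negative abundance for taxon {taxon!r}")
        if biomass == 0:
            continue
        if taxon not in D:
            raise KeyError(f"taxon {taxon!r} not in the patristic matrix")
        taxa.append(taxon)
        w.append(biomass)
    return taxa, np.asarray(w, dtype=float)


def interspecific_mpd(
    D: PatristicMatrix,
    abundances: Mapping[str, float],
    plot: str | None = None,
) -> MPDResult:
    """Abundance-weighted interspecific MPD of one community.

    ``abundances`` maps taxon -> biomass (any positive scale; weights are
    normalized internally, so raw and relative biomass give the same
    value).  Fewer than two positive-abundance taxa yields an undefined
    result (flag, not an exception): no interspecific pair exists.
    """
    taxa, w = _positive_weights(abundances, D)
    if len(taxa) < 2:
        return MPDResult(
            value=float("nan"),
            n_taxa=len(taxa),
            plot=plot,
            defined=False,
            reason=f"{len(taxa)} taxa with positive abundance (need >= 2)",
        )
    p = w / w.sum()
    d = D.submatrix(taxa).values
    num = float(p @ d @ p)  # diagonal of d is 0, so i = j pairs drop out
    den = 1.0 - float(p @ p)
    return MPDResult(value=num / den, n_taxa=len(taxa), plot=plot)


def delta_inter_mpd(
    weeds: Mapping[str, float],
    cover: Sequence[tuple[str, float]],
    D: PatristicMatrix,
) -> float:
    """MPD shift caused by adding the cover taxa to a weed community.

    ``cover`` is a list of (taxon, biomass); a two-species mixture simply
    contributes both components, each with its own biomass.  A cover taxon
    that also occurs among the weeds (a volunteer) has the biomasses
    summed.  All-zero cover biomass gives 0 with a warning: the combined
    community equals the weeds.
    """
    base = interspecific_mpd(D, weeds)
    if not base.defined:
        raise ValueError(f"weed community undefined for MPD: {base.reason}")
    total_cover = sum(b for _, b in cover)
    if total_cover == 0:
        logger.warning("cover biomass is zero; delta MPD = 0 by definition")
        return 0.0
    combined = dict(weeds)
    for taxon, biomass in cover:
        combined[taxon] = combined.get(taxon, 0.0) + biomass
    return interspecific_mpd(D, combined).value - base.value


def relativized_inter_mpd(
    cover_weeds: Mapping[str, float],
    control_weeds: Mapping[str, float],
    cover: Sequence[tuple[str, float]],
    D: PatristicMatrix,
    cover_plot: str = "cover",
    control_plot: str = "control",
) -> RelativizedMPDResult:
    """Relativized phylogenetic distance between a cover crop and its weeds.

    Both delta terms use the *same* cover taxa with the *same* biomass
    (taken from the cover plot), so their difference isolates the shift in
    the weed community itself.  Either weed community with fewer than two
    resolvable taxa flags the result undefined.
    """
    cover_taxa = tuple(t for t, _ in cover)
    cover_w = tuple(float(b) for _, b in cover)
    for name, weeds in (("cover", cover_weeds), ("control", control_weeds)):
        n_pos = sum(1 for b in weeds.values() if b > 0)
        if n_pos < 2:
            return RelativizedMPDResult(
                cover_plot=cover_plot,
                control_plot=control_plot,
                mpd_weeds_cover=float("nan"),
                mpd_weeds_control=float("nan"),
                delta_cover=float("nan"),
                delta_control=float("nan"),
                relativized=float("nan"),
                cover_taxa=cover_taxa,
                cover_weights=cover_w,
                defined=False,
                reason=f"{name} weed community has {n_pos} taxa (need >= 2)",
            )
    mpd_cov = interspecific_mpd(D, cover_weeds).value
    mpd_ctl = interspecific_mpd(D, control_weeds).value
    d_cov = delta_inter_mpd(cover_weeds, cover, D)
    d_ctl = delta_inter_mpd(control_weeds, cover, D)
    return RelativizedMPDResult(
        cover_plot=cover_plot,
        control_plot=control_plot,
        mpd_weeds_cover=mpd_cov,
        mpd_weeds_control=mpd_ctl,
        delta_cover=d_cov,
        delta_control=d_ctl,
        relativized=d_cov - d_ctl,
        cover_taxa=cover_taxa,
        cover_weights=cover_w,
    )


# -- table-level drivers -------------------------------------------------


def _plot_weed_abundances(
    table: CommunityTable, D: PatristicMatrix
) -> tuple[dict[str, dict[str, float]], int]:
    """Per plot: weed taxon -> biomass, restricted to phylogeny tips.

    Taxa absent from the matrix (unknowns, unresolved names) are excluded
    here and counted; they never enter MPD.
    """
    weeds = table.weeds()
    on_tree = weeds["taxon"].map(lambda t: t in D)
    n_excluded = int((~on_tree).sum())
    if n_excluded:
        dropped = sorted(weeds.loc[~on_tree, "taxon"].unique())
        logger.info(
            "excluded %d weed record(s) with taxa off the phylogeny: %s",
            n_excluded,
            ", ".join(dropped),
        )
    weeds = weeds[on_tree]
    out: dict[str, dict[str, float]] = {p: {} for p in table.plots().index}
    for row in weeds.itertuples():
        out[row.plot][row.taxon] = out[row.plot].get(row.taxon, 0.0) + row.biomass
    return out, n_excluded


def mpd_by_plot(
    table: CommunityTable,
    D: PatristicMatrix,
    include_cover: bool = False,
) -> pd.DataFrame:
    """Per-plot interspecific MPD (weeds only by default).

    Returns one row per plot with design metadata, the MPD value, the
    number of taxa used, and a ``defined`` flag; undefined plots are
    carried with the flag rather than dropped.
    """
    if all(t not in D for t in table.weeds()["taxon"].unique()):
        raise ValueError(
            "no weed taxon is on the phylogeny; MPD is undefined everywhere"
        )
    abund, _ = _plot_weed_abundances(table, D)
    covers = table.cover_taxa_by_plot() if include_cover else {}
    meta = table.plots()
    rows = []
    for plot in meta.index:
        community = dict(abund.get(plot, {}))
        for taxon, biomass in covers.get(plot, []):
            if taxon in D:
                community[taxon] = community.get(taxon, 0.0) + biomass
        res = interspecific_mpd(D, community, plot=plot)
        rows.append(
            {
                "plot": plot,
                **meta.loc[plot].to_dict(),
                "mpd": res.value,
                "n_taxa": res.n_taxa,
                "defined": res.defined,
            }
        )
    return pd.DataFrame(rows)


def relativize_by_pairing(
    table: CommunityTable,
    D: PatristicMatrix,
    cover_weight: str = "measured",
    pairing: str = "block",
) -> pd.DataFrame:
    """Relativized MPD for every cover plot against its paired control.

    pairing
        ``block`` (default): each cover plot pairs with the control plot
        of its own site-year x block, respecting the randomized complete
        block design.  ``site-pooled``: pairs against the biomass-summed
        control community of the whole site-year.
    cover_weight
        ``measured`` (default): the cover plot's measured cover biomass
        enters both delta terms.  ``unit``: each cover taxon is instead
        assigned the mean positive weed biomass of the community it joins,
        an equal-footing alternative.
    """
    if pairing not in ("block", "site-pooled"):
        raise ValueError(f"unknown pairing mode {pairing!r}")
    if cover_weight not in ("measured", "unit"):
        raise ValueError(f"unknown cover_weight mode {cover_weight!r}")
    abund, _ = _plot_weed_abundances(table, D)
    meta = table.plots()
    covers = table.cover_taxa_by_plot()
    controls = meta[meta["treatment"] == CONTROL]
    control_lookup: dict[tuple, tuple[str, dict[str, float]]] = {}
    if pairing == "block":
        for plot, row in controls.iterrows():
            control_lookup[(row["site"], row["year"], row["block"])] = (
                plot,
                abund.get(plot, {}),
            )
    else:
        for (site, year), grp in controls.groupby(["site", "year"]):
            pooled: dict[str, float] = {}
            for plot in grp.index:
                for taxon, biomass in abund.get(plot, {}).items():
                    pooled[taxon] = pooled.get(taxon, 0.0) + biomass
            key_plots = "+".join(sorted(grp.index))
            for block in meta.loc[
                (meta["site"] == site) & (meta["year"] == year), "block"
            ].unique():
                control_lookup[(site, year, block)] = (key_plots, pooled)

    rows = []
    for plot, row in meta.iterrows():
        if row["treatment"] == CONTROL:
            continue
        key = (row["site"], row["year"], row["block"])
        if key not in control_lookup:
            logger.warning("no control pairing for cover plot %s; skipped", plot)
            continue
        control_plot, control_weeds = control_lookup[key]
        cover = [(t, b) for t, b in covers.get(plot, []) if t in D]
        if not cover:
            logger.warning("cover plot %s has no on-tree cover taxa; skipped", plot)
            continue
        cover_weeds = abund.get(plot, {})
        if cover_weight == "unit":
            cover = _unit_weight_cover(cover, cover_weeds)
        res = relativized_inter_mpd(
            cover_weeds,
            control_weeds,
            cover,
            D,
            cover_plot=plot,
            control_plot=control_plot,
        )
        rows.append(
            {
                "cover_plot": plot,
                "control_plot": control_plot,
                "site": row["site"],
                "year": row["year"],
                "block": row["block"],
                "treatment": row["treatment"],
                "mpd_weeds_cover": res.mpd_weeds_cover,
                "mpd_weeds_control": res.mpd_weeds_control,
                "delta_cover": res.delta_cover,
                "delta_control": res.delta_control,
                "relativized": res.relativized,
                "defined": res.defined,
                "reason": res.reason,
            }
        )
    out = pd.DataFrame(rows)
    n_undef = int((~out["defined"]).sum()) if len(out) else 0
    if n_undef:
        logger.info("%d pairing(s) undefined and flagged (not zero-filled)", n_undef)
    return out


def _unit_weight_cover(
    cover: Sequence[tuple[str, float]], weeds: Mapping[str, float]
) -> list[tuple[str, float]]:
    pos = [b for b in weeds.values() if b > 0]
    w = float(np.mean(pos)) if pos else 1.0
    return [(t, w) for t, _ in cover]
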