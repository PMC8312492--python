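"""Photo-quadrat point counts to percent cover, bleaching extent, diversity.

Records enter already annotated (one row per random point on a photo,
CPCe-style): site, area, survey, transect, photo, point, OTU, bleaching
state. Percent cover of a category in any grouping cell is 100 x the
share of that cell's points falling on the category, so covers over an
exhaustive partition always sum to 100.

Bleaching extent uses only the "bleached" (totally bleached) state;
"discolored" points count toward an OTU's live cover but not toward the
headline extent. The assemblage-scale denominator is the points whose
OTU group is scleractinian or octocoral.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BLEACH_STATES",
    "GROUPS",
    "BleachingSummary",
    "DiversitySummary",
    "cover_from_points",
    "aggregate_categories",
    "bleaching_extent",
    "diversity_summary",
    "percent_change",
    "richness_change_table",
    "transect_matrix",
]

BLEACH_STATES = ("none", "discolored", "bleached", "not_applicable")
GROUPS = (
    "scleractinian", "octocoral", "algae", "hydrozoan", "zoantharian",
    "sea_anemone", "sponge", "ascidian", "other_life", "abiotic",
)
#: groups whose points form the coral-assemblage denominator for bleaching
ASSEMBLAGE_GROUPS = ("scleractinian", "octocoral")


@dataclass(frozen=True)
class BleachingSummary:
    """Bleaching extent at one scope.

    ``per_otu`` columns: otu_id, n_bleached, share_of_all_bleached_points
    (% of the scope's bleached points on this OTU; sums to 100 when any
    point bleached), bleached_fraction_of_own_cover (% of the OTU's own
    points that are bleached). ``community_bleached`` is the % of all
    points bleached; ``assemblage_bleached`` restricts the denominator to
    scleractinian + octocoral points.
    """

    scope: str
    per_otu: pd.DataFrame
    community_bleached: float
    assemblage_bleached: float
    n_points: int
    n_bleached: int


@dataclass(frozen=True)
class DiversitySummary:
    scope: str
    otu_richness: int
    shannon: float  # nats
    alpha_richness_mean: float  # mean per-site-per-survey richness
    alpha_richness_sd: float


def _check_taxonomy(records: pd.DataFrame, taxonomy: pd.DataFrame) -> None:
    if taxonomy["otu_id"].duplicated().any():
        dups = taxonomy.loc[taxonomy["otu_id"].duplicated(), "otu_id"].tolist()
        raise ValueError(f"duplicate otu_id rows in taxonomy: {dups}")
    unknown = sorted(set(records["otu_id"]) - set(taxonomy["otu_id"]))
    if unknown:
        raise ValueError(f"records contain OTUs missing from taxonomy: {unknown}")


def cover_from_points(
    records: pd.DataFrame,
    taxonomy: pd.DataFrame,
    group_by: list[str],
    *,
    category: str = "otu_id",
) -> pd.DataFrame:
    """Percent cover per grouping cell.

    ``group_by`` is any subset of (area, site_id, survey_id, transect);
    ``category`` is ``otu_id`` or a taxonomy column (group,
    major_category, morphotype). Returns long-form rows
    ``*group_by, category, n_points, percent_cover`` where percent_cover
    = 100 x points on category / total points in the cell.
    """
    _check_taxonomy(records, taxonomy)
    rec = records.merge(
        taxonomy.drop(columns=["label"], errors="ignore"), on="otu_id", how="left"
    )
    if category == "morphotype":
        rec[category] = rec[category].fillna("none")
    counts = (
        rec.groupby([*group_by, category], sort=True, observed=True)
        .size()
        .rename("n_points")
        .reset_index()
    )
    totals = counts.groupby(group_by, observed=True)["n_points"].transform("sum")
    counts["percent_cover"] = 100.0 * counts["n_points"] / totals
    return counts


def aggregate_categories(
    cover: pd.DataFrame, taxonomy: pd.DataFrame, level: str
) -> pd.DataFrame:
    """Sum an OTU-level cover table into taxonomy classes.

    ``level`` is ``major_category``, ``morphotype`` or ``group``. OTUs
    with no morphotype are routed to a ``"none"`` class so the partition
    stays exhaustive and covers still sum to 100 per cell.
    """
    tax = taxonomy.set_index("otu_id")[level]
    if level == "morphotype":
        tax = tax.fillna("none")
    missing = sorted(set(cover["otu_id"]) - set(tax.index))
    if missing:
        raise ValueError(f"taxonomy lacks {level} for OTUs: {missing}")
    out = cover.copy()
    out[level] = out["otu_id"].map(tax)
    keys = [c for c in out.columns if c not in ("otu_id", level, "n_points", "percent_cover")]
    return (
        out.groupby([*keys, level], observed=True)[["n_points", "percent_cover"]]
        .sum()
        .reset_index()
    )


def bleaching_extent(
    records: pd.DataFrame, taxonomy: pd.DataFrame, scope: str = "all"
) -> BleachingSummary:
    """Bleaching extent over the given records.

    Only ``bleach_state == "bleached"`` counts; callers subset the records
    to the scope (e.g. one survey, one area) before calling.
    """
    if records.empty:
        raise ValueError("no records in scope")
    _check_taxonomy(records, taxonomy)
    rec = records.merge(taxonomy[["otu_id", "group"]], on="otu_id", how="left")
    bleached = rec["bleach_state"] == "bleached"
    n_points = len(rec)
    n_bleached = int(bleached.sum())

    per_otu = (
        rec.assign(is_bleached=bleached)
        .groupby("otu_id")
        .agg(n_points=("is_bleached", "size"), n_bleached=("is_bleached", "sum"))
        .reset_index()
    )
    per_otu["share_of_all_bleached_points"] = (
        100.0 * per_otu["n_bleached"] / n_bleached if n_bleached else 0.0
    )
    per_otu["bleached_fraction_of_own_cover"] = (
        100.0 * per_otu["n_bleached"] / per_otu["n_points"]
    )

    assemblage = rec["group"].isin(ASSEMBLAGE_GROUPS)
    n_assemblage = int(assemblage.sum())
    assemblage_bleached = (
        100.0 * int((bleached & assemblage).sum()) / n_assemblage if n_assemblage else 0.0
    )
    return BleachingSummary(
        scope=scope,
        per_otu=per_otu,
        community_bleached=100.0 * n_bleached / n_points,
        assemblage_bleached=assemblage_bleached,
        n_points=n_points,
        n_bleached=n_bleached,
    )


def diversity_summary(
    records: pd.DataFrame, taxonomy: pd.DataFrame, scope: str = "all"
) -> DiversitySummary:
    """OTU richness, Shannon index (natural log) and alpha-richness.

    Alpha diversity is operationalised as the mean +- sample SD of
    per-site-per-survey OTU richness within the scope.
    """
    if records.empty:
        raise ValueError("no records in scope")
    _check_taxonomy(records, taxonomy)
    counts = records["otu_id"].value_counts()
    p = counts / counts.sum()
    shannon = float(-(p * np.log(p)).sum())
    per_cell = records.groupby(["site_id", "survey_id"])["otu_id"].nunique()
    sd = float(per_cell.std(ddof=1)) if len(per_cell) > 1 else float("nan")
    return DiversitySummary(
        scope=scope,
        otu_richness=int(counts.size),
        shannon=shannon,
        alpha_richness_mean=float(per_cell.mean()),
        alpha_richness_sd=sd,
    )


def percent_change(before: float, after: float) -> float:
    """Signed relative change, %: 100 * (after - before) / before."""
    if before == 0:
        raise ValueError("relative change undefined for before == 0")
    return 100.0 * (after - before) / before


def richness_change_table(
    records: pd.DataFrame,
    taxonomy: pd.DataFrame,
    groups: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-area, per-survey OTU richness by broad taxon group.

    ``groups`` maps a taxonomy ``group`` value to an output column name;
    the default mirrors the usual monitoring summary (scleractinians,
    octocorals, macro-algae, other life). Surveys never conducted in an
    area appear as missing cells (NaN), not zero.
    """
    if groups is None:
        groups = {
            "scleractinian": "scleractinians",
            "octocoral": "octocorals",
            "algae": "macro_algae",
            "other_life": "other_life",
        }
    _check_taxonomy(records, taxonomy)
    rec = records.merge(taxonomy[["otu_id", "group"]], on="otu_id", how="left")
    rec = rec[rec["group"].isin(groups)]
    rich = (
        rec.groupby(["area", "survey_id", "group"])["otu_id"]
        .nunique()
        .unstack("group")
        .rename(columns=groups)
    )
    # pivot on conducted surveys only: missing area-surveys stay absent
    observed = records.groupby(["area", "survey_id"]).size().index
    rich = rich.reindex(observed)
    return rich.reset_index()


def transect_matrix(
    records: pd.DataFrame, taxonomy: pd.DataFrame
) -> pd.DataFrame:
    """Transect x OTU proportion matrix with factor columns.

    Rows are (site_id, area, survey_id, transect) observations, columns
    OTUs, values proportion cover in [0, 1]. This is the sampling-unit
    table the multivariate statistics operate on.
    """
    cover = cover_from_points(
        records, taxonomy, ["area", "site_id", "survey_id", "transect"]
    )
    wide = cover.pivot_table(
        index=["area", "site_id", "survey_id", "transect"],
        columns="otu_id",
        values="percent_cover",
        fill_value=0.0,
    )
    return (wide / 100.0).reset_index()
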