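"""From raw ASV counts to a standardized date x taxon community matrix.

The stages, in pipeline order:

1. :func:`assign_taxonomy` — BLAST-style hit tables to per-ASV taxa: a
   single best-matching species at >= 98% identity gives a species-level
   call; equal-identity ties collapse to the lowest common rank (genus,
   then family); anything unresolvable at the family level is excluded.
2. :func:`control_filter_threshold` / :func:`apply_control_filter` —
   contamination filtering driven by the DNA-extraction and PCR blanks:
   ASVs whose field-sample total falls below the mean of the non-zero
   per-ASV control sums are removed.
3. :func:`standardize_depth` — proportional scaling of every field sample
   to the minimum sequencing depth.
4. :func:`aggregate_to_dates` — sum standardized reads over ASVs of the
   same taxon and over same-date field replicates, pooling species pairs
   the marker cannot distinguish.
5. :func:`checklist_means` — per-date mean checklist counts for the
   community-science comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import AsvTable, CommunityMatrix, ConfigError

__all__ = [
    "HitRecord",
    "TaxAssignment",
    "DEFAULT_POOLS",
    "SPECIES_IDENTITY_THRESHOLD",
    "assign_taxonomy",
    "control_filter_threshold",
    "apply_control_filter",
    "standardize_depth",
    "aggregate_to_dates",
    "checklist_means",
]

logger = logging.getLogger(__name__)

#: Minimum percent identity for a species-level assignment.
SPECIES_IDENTITY_THRESHOLD = 98.0
#: How many top hits (by score, then identity) are considered per ASV.
TOP_N_HITS = 5

#: Species pairs the ND2 metabarcodes cannot distinguish; their read and
#: survey totals are pooled into one taxon each.
DEFAULT_POOLS: tuple[tuple[str, str], ...] = (
    ("Anas platyrhynchos", "Anas rubripes"),  # mallard / American black duck
    ("Cygnus columbianus", "Cygnus buccinator"),  # tundra / trumpeter swan
    ("Aythya marila", "Aythya affinis"),  # greater / lesser scaup
)


@dataclass(frozen=True)
class HitRecord:
    """One candidate reference match for one ASV (BLAST-tabular style)."""

    asv_id: str
    subject_species: str
    subject_genus: str
    subject_family: str
    pct_identity: float
    score: float

    def __post_init__(self) -> None:
        if not (0 <= self.pct_identity <= 100):
            raise ValueError(f"pct_identity out of [0, 100]: {self.pct_identity}")


@dataclass(frozen=True)
class TaxAssignment:
    """The taxonomic call for one ASV and how it was reached."""

    asv_id: str
    rank: str  # species | genus | family | excluded
    name: str
    best_identity: float
    basis: str  # single_species_ge98 | tie_lca_genus | tie_lca_family | below_family_excluded | no_hits


def _assign_one(asv_id: str, group: pd.DataFrame) -> TaxAssignment:
    top = group.sort_values(
        ["score", "pct_identity"], ascending=False, kind="mergesort"
    ).head(TOP_N_HITS)
    best_ident = float(top["pct_identity"].max())
    tied = top[top["pct_identity"] == best_ident]
    species = set(tied["subject_species"])
    genera = set(tied["subject_genus"])
    families = set(tied["subject_family"])

    if len(species) == 1 and best_ident >= SPECIES_IDENTITY_THRESHOLD:
        return TaxAssignment(asv_id, "species", species.pop(), best_ident, "single_species_ge98")
    # equal-identity ties (or a sub-threshold best hit) drop to the lowest
    # common rank among the tied hits
    if len(genera) == 1:
        return TaxAssignment(asv_id, "genus", genera.pop(), best_ident, "tie_lca_genus")
    if len(families) == 1:
        return TaxAssignment(asv_id, "family", families.pop(), best_ident, "tie_lca_family")
    return TaxAssignment(asv_id, "excluded", "", best_ident, "below_family_excluded")


def assign_taxonomy(
    hits: pd.DataFrame, asv_ids: list[str] | None = None
) -> list[TaxAssignment]:
    """Assign each ASV a taxon from its hit table.

    Parameters
    ----------
    hits
        Columns ``asv_id subject_species subject_genus subject_family
        pct_identity score``; more than five hits per ASV are tolerated
        (truncated to the top five by score, then identity).
    asv_ids
        Optional complete ASV roster; ASVs with no hits at all are
        recorded as excluded with basis ``no_hits``.

    Every ASV receives exactly one assignment.
    """
    required = {"asv_id", "subject_species", "subject_genus", "subject_family", "pct_identity", "score"}
    missing = required - set(hits.columns)
    if missing:
        raise ConfigError(f"hit table missing columns: {sorted(missing)}")
    ident = pd.to_numeric(hits["pct_identity"], errors="raise")
    if ((ident < 0) | (ident > 100)).any():
        raise ConfigError("pct_identity out of [0, 100]")

    out = [_assign_one(aid, grp) for aid, grp in hits.groupby("asv_id", sort=True)]
    seen = {a.asv_id for a in out}
    for aid in asv_ids or []:
        if aid not in seen:
            out.append(TaxAssignment(aid, "excluded", "", 0.0, "no_hits"))
    out.sort(key=lambda a: a.asv_id)
    return out


def assignments_frame(assignments: list[TaxAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [(a.asv_id, a.rank, a.name, a.best_identity, a.basis) for a in assignments],
        columns=["asv_id", "rank", "name", "best_identity", "basis"],
    )


def control_filter_threshold(table: AsvTable, mode: str = "per_asv") -> float:
    """Contamination-filter threshold from the extraction and PCR blanks.

    ``mode='per_asv'`` (default): sum each ASV's reads across all
    extraction and PCR blanks, then average over the ASVs whose sum is
    non-zero.  ``mode='per_control'``: average the per-control column
    totals over controls with non-zero totals (the alternative reading of
    "average ... summed across the negative controls").  Returns 0 when
    the controls are clean.
    """
    controls = table.control_samples
    if not controls:
        raise ConfigError(
            "no extraction_blank or pcr_blank samples: the control filter cannot be computed"
        )
    sub = table.counts[controls]
    if mode == "per_asv":
        sums = sub.sum(axis=1)
    elif mode == "per_control":
        sums = sub.sum(axis=0)
    else:
        raise ConfigError(f"unknown control_threshold_mode {mode!r}")
    nonzero = sums[sums > 0]
    return float(nonzero.mean()) if len(nonzero) else 0.0


def apply_control_filter(table: AsvTable, threshold: float) -> AsvTable:
    """Drop ASVs whose total reads across *field* samples fall below the
    threshold ("fewer than" is strict: a total equal to the threshold is
    retained).  Blank columns are carried through untouched for QC."""
    if threshold < 0:
        raise ConfigError("threshold must be >= 0")
    field_totals = table.counts[table.field_samples].sum(axis=1)
    keep = field_totals >= threshold
    removed = int((~keep).sum())
    if removed:
        logger.info("control filter at %.3f removed %d/%d ASVs", threshold, removed, len(keep))
    return AsvTable(table.counts.loc[keep].copy(), table.meta.copy())


def standardize_depth(table: AsvTable) -> AsvTable:
    """Proportionally scale each field sample to the minimum field depth.

    Each field column j is multiplied by ``D_min / D_j``; values are left
    fractional.  Field samples with zero depth are dropped with a warning.
    Idempotent: a second application is the identity.
    """
    field = table.field_samples
    if not field:
        raise ConfigError("no field samples to standardize")
    depths = table.counts[field].sum(axis=0)
    zero = depths[depths == 0].index.tolist()
    if zero:
        logger.warning("dropping zero-depth field samples: %s", zero)
        field = [s for s in field if s not in zero]
        if not field:
            raise ConfigError("all field samples have zero depth")
        depths = depths.drop(zero)
    dmin = float(depths.min())
    counts = table.counts.drop(columns=zero).astype(float)
    counts[field] = counts[field] * (dmin / depths)
    meta = table.meta.drop(index=zero)
    return AsvTable(counts, meta)


def aggregate_to_dates(
    table: AsvTable,
    assignments: list[TaxAssignment],
    pools: tuple[tuple[str, str], ...] = DEFAULT_POOLS,
) -> CommunityMatrix:
    """Collapse the (filtered, standardized) ASV table to date x taxon.

    Standardized reads are summed over ASVs assigned to the same taxon,
    then over same-date field replicates; species pairs in ``pools`` are
    summed into a single pooled taxon named "A/B".  The grand total over
    field samples is conserved up to excluded ASVs (which must have been
    dropped upstream or carry their own rows here — excluded assignments
    are skipped with a log entry).
    """
    amap = {a.asv_id: a for a in assignments}
    field = table.field_samples
    if not field:
        raise ConfigError("no field samples to aggregate")

    taxon_of: dict[str, str] = {}
    for aid in table.counts.index:
        a = amap.get(aid)
        if a is None or a.rank == "excluded":
            logger.info("ASV %s has no usable assignment; dropped from aggregation", aid)
            continue
        taxon_of[aid] = a.name

    sub = table.counts.loc[list(taxon_of), field]
    by_taxon = sub.groupby(pd.Series(taxon_of), sort=True).sum()

    dates = table.meta.loc[field, "date"]
    by_date = by_taxon.T.groupby(dates).sum()
    by_date = by_date.sort_index()

    for a, b in pools:
        members = [m for m in (a, b) if m in by_date.columns]
        if not members:
            logger.info("pool (%s, %s) names no assigned taxon; skipped", a, b)
            continue
        pooled = f"{a}/{b}"
        by_date[pooled] = by_date[members].sum(axis=1)
        by_date = by_date.drop(columns=members)

    return CommunityMatrix(by_date, provenance="standardized_reads")


def pool_community(
    matrix: CommunityMatrix, pools: tuple[tuple[str, str], ...] = DEFAULT_POOLS
) -> CommunityMatrix:
    """Apply the same species-pair pooling to a survey-side matrix so both
    sides of a comparison share taxon labels."""
    values = matrix.values.copy()
    for a, b in pools:
        members = [m for m in (a, b) if m in values.columns]
        if not members:
            continue
        pooled = f"{a}/{b}"
        values[pooled] = values[members].sum(axis=1)
        values = values.drop(columns=members)
    return CommunityMatrix(values, provenance=matrix.provenance)


def checklist_means(
    checklists: pd.DataFrame, dates: list | None = None
) -> CommunityMatrix:
    """Per-(date, species) mean count across that date's checklists.

    A species absent from a checklist counts as 0 in that checklist
    (checklists are complete: everything observed is reported).  The
    per-date checklist count is kept in ``extra['n_checklists']`` for the
    downstream >= 3-checklist filter.  Requested dates with no checklists
    are excluded with a warning.
    """
    required = {"checklist_id", "date", "species", "count"}
    missing = required - set(checklists.columns)
    if missing:
        raise ConfigError(f"checklist table missing columns: {sorted(missing)}")
    cl = checklists.copy()
    cl["date"] = pd.to_datetime(cl["date"])
    if dates is not None:
        wanted = pd.to_datetime(list(dates))
        have = set(cl["date"])
        for d in wanted:
            if d not in have:
                logger.warning("no checklists on %s; date excluded", d.date())
        cl = cl[cl["date"].isin(set(wanted) & have)]
    if cl.empty:
        raise ConfigError("no checklists on any requested date")

    n_per_date = cl.groupby("date")["checklist_id"].nunique()
    # absent species count as zero: divide per-date species totals by the
    # number of checklists rather than averaging only reported rows
    totals = cl.pivot_table(
        index="date", columns="species", values="count", aggfunc="sum", fill_value=0
    )
    means = totals.div(n_per_date, axis=0)
    out = CommunityMatrix(means, provenance="checklist_mean")
    out.extra["n_checklists"] = n_per_date
    return out


def focal_matrix(focal: pd.DataFrame) -> CommunityMatrix:
    """Pivot a ``date species count`` focal-survey table to date x species."""
    f = focal.copy()
    f["date"] = pd.to_datetime(f["date"])
    values = f.pivot_table(
        index="date", columns="species", values="count", aggfunc="sum", fill_value=0
    )
    return CommunityMatrix(values, provenance="focal_counts")
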