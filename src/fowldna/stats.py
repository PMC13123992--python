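"""Correlation statistics linking eDNA read tables to visual surveys.

Abundances span several orders of magnitude, so comparisons between read
totals and bird counts use Pearson correlation on log-transformed vectors
(with a +1 pseudocount for structural zeros).  Within-date cross-species
concordance uses Kendall tau-b (count data are tied).  Significance is a
one-tailed p < alpha for *positive* association throughout.  The temporal
structure is summarised as a correlation network over date-nodes: an edge
joins two dated community snapshots when their log-log correlation is both
significant and at least a threshold (default r >= 0.6), with
visual-visual and visual-eDNA edges considered (not eDNA-eDNA, unless
asked for).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import CommunityMatrix, ConfigError

__all__ = [
    "CorrelationResult",
    "loglog_pearson",
    "per_species_timecourse",
    "per_date_kendall",
    "lagged_correlations",
    "build_network",
    "checklist_concordance",
]

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
DEFAULT_EDGE_THRESHOLD = 0.6
DEFAULT_PSEUDOCOUNT = 1.0


@dataclass(frozen=True)
class CorrelationResult:
    """One correlation with its one-tailed p for positive association."""

    kind: str  # pearson_loglog | kendall
    coefficient: float
    p_one_tail: float
    n: int
    lag_days: int | None = None
    undefined: bool = False  # zero variance after transform

    @property
    def significant(self) -> bool:
        return (not self.undefined) and self.p_one_tail < DEFAULT_ALPHA


def loglog_pearson(
    x, y, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> CorrelationResult:
    """Pearson correlation of log(x + pseudocount) vs log(y + pseudocount).

    The one-tailed p for positive association comes from the t transform
    ``t = r sqrt((n-2) / (1-r^2))`` with n-2 degrees of freedom.  A
    zero-variance vector after the transform yields an explicitly flagged
    undefined result rather than NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ConfigError("x and y must be 1-d vectors of equal length")
    n = len(x)
    if n < 3:
        raise ConfigError("need at least 3 observations")
    if (x + pseudocount <= 0).any() or (y + pseudocount <= 0).any():
        raise ConfigError("values + pseudocount must be positive for the log transform")
    lx, ly = np.log(x + pseudocount), np.log(y + pseudocount)
    if np.ptp(lx) == 0 or np.ptp(ly) == 0:
        return CorrelationResult("pearson_loglog", np.nan, np.nan, n, undefined=True)
    r = float(np.corrcoef(lx, ly)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0 if r > 0 else 1.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(sps.t.sf(t, df=n - 2))
    return CorrelationResult("pearson_loglog", r, p, n)


def kendall_tau(x, y, lag_days: int | None = None) -> CorrelationResult:
    """Kendall tau-b with one-tailed p for positive association."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise ConfigError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult("kendall", np.nan, np.nan, n, lag_days, undefined=True)
    res = sps.kendalltau(x, y, variant="b", alternative="greater")
    return CorrelationResult("kendall", float(res.statistic), float(res.pvalue), n, lag_days)


def _shared_taxa(a: CommunityMatrix, b: CommunityMatrix) -> list[str]:
    return sorted(set(a.taxa) & set(b.taxa))


def per_species_timecourse(
    reads: CommunityMatrix,
    surveys: CommunityMatrix,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Log-log correlation across dates, one row per shared taxon.

    Columns: taxon, r, p_one_tail, p_bh (Benjamini-Hochberg adjusted, for
    transparency; the significance flag uses the raw one-tailed p), n,
    undefined, significant.
    """
    dates = reads.dates.intersection(surveys.dates)
    if len(dates) < 3:
        raise ConfigError("need at least 3 shared dates")
    rows = []
    for taxon in _shared_taxa(reads, surveys):
        res = loglog_pearson(
            reads.values.loc[dates, taxon], surveys.values.loc[dates, taxon], pseudocount
        )
        rows.append(
            {
                "taxon": taxon,
                "r": res.coefficient,
                "p_one_tail": res.p_one_tail,
                "n": res.n,
                "undefined": res.undefined,
            }
        )
    skipped = (set(reads.taxa) ^ set(surveys.taxa))
    for taxon in sorted(skipped):
        logger.info("taxon %s present on one side only; skipped", taxon)
    out = pd.DataFrame(rows)
    if out.empty:
        raise ConfigError("no shared taxa")
    out["p_bh"] = _benjamini_hochberg(out["p_one_tail"].to_numpy())
    out["significant"] = (~out["undefined"]) & (out["p_one_tail"] < alpha)
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        out[ok] = sps.false_discovery_control(p[ok], method="bh")
    return out


def per_date_kendall(
    reads: CommunityMatrix, surveys: CommunityMatrix, date
) -> CorrelationResult:
    """Kendall tau-b across taxa between reads and counts on one date."""
    date = pd.Timestamp(date)
    if date not in reads.dates or date not in surveys.dates:
        raise ConfigError(f"date {date.date()} absent from one of the matrices")
    taxa = _shared_taxa(reads, surveys)
    if len(taxa) < 3:
        raise ConfigError("need at least 3 shared taxa")
    return kendall_tau(reads.values.loc[date, taxa], surveys.values.loc[date, taxa])


def lagged_correlations(
    reads: CommunityMatrix,
    surveys: CommunityMatrix,
    max_lag: int = 5,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> dict[str, pd.DataFrame]:
    """Correlate eDNA on date t against surveys on t - lag, lag = 0..max_lag.

    Returns two tables:

    * ``per_date`` — rows (lag, date): cross-species Kendall tau-b between
      reads on t and survey counts on t - lag;
    * ``per_species`` — rows (lag, taxon): log-log Pearson across sampling
      dates of reads on t vs surveys on t - lag.

    Lagged dates missing from the survey matrix are skipped and recorded in
    ``per_date`` with ``skipped=True`` rows.
    """
    if max_lag < 0:
        raise ConfigError("max_lag must be >= 0")
    taxa = _shared_taxa(reads, surveys)
    if len(taxa) < 3:
        raise ConfigError("need at least 3 shared taxa")

    per_date_rows = []
    per_species_rows = []
    for lag in range(max_lag + 1):
        offset = pd.Timedelta(days=lag)
        usable = [t for t in reads.dates if (t - offset) in surveys.dates]
        for t in reads.dates:
            if t not in usable:
                logger.info("lag %d: no survey on %s; skipped", lag, (t - offset).date())
                per_date_rows.append(
                    {"lag": lag, "date": t, "tau": np.nan, "p_one_tail": np.nan,
                     "n_taxa": 0, "skipped": True}
                )
                continue
            res = kendall_tau(
                reads.values.loc[t, taxa],
                surveys.values.loc[t - offset, taxa],
                lag_days=lag,
            )
            per_date_rows.append(
                {"lag": lag, "date": t, "tau": res.coefficient,
                 "p_one_tail": res.p_one_tail, "n_taxa": res.n, "skipped": False}
            )
        if len(usable) >= 3:
            r_dates = pd.DatetimeIndex(usable)
            for taxon in taxa:
                res = loglog_pearson(
                    reads.values.loc[r_dates, taxon],
                    surveys.values.loc[r_dates - offset, taxon],
                    pseudocount,
                )
                per_species_rows.append(
                    {"lag": lag, "taxon": taxon, "r": res.coefficient,
                     "p_one_tail": res.p_one_tail, "n_dates": res.n,
                     "undefined": res.undefined}
                )
    return {
        "per_date": pd.DataFrame(per_date_rows),
        "per_species": pd.DataFrame(per_species_rows),
    }


def best_lag(lag_tables: dict[str, pd.DataFrame]) -> int:
    """The lag maximising the mean per-date Kendall tau."""
    per_date = lag_tables["per_date"]
    means = per_date[~per_date["skipped"]].groupby("lag")["tau"].mean()
    return int(means.idxmax())


def build_network(
    visual: CommunityMatrix,
    reads: CommunityMatrix,
    threshold: float = DEFAULT_EDGE_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    include_edna_edna: bool = False,
) -> nx.Graph:
    """Date-node correlation network over community snapshots.

    Nodes are (date, layer) with layer 'visual' or 'eDNA'; candidate edges
    are all visual-visual date pairs and all visual-eDNA date pairs
    (eDNA-eDNA only when ``include_edna_edna``).  An edge is kept iff the
    log-log Pearson correlation of the two community vectors across shared
    taxa is positive, >= ``threshold``, and one-tailed significant at
    ``alpha``; edge weights are r.
    """
    if not (0 < threshold <= 1):
        raise ConfigError("threshold must be in (0, 1]")
    taxa = _shared_taxa(visual, reads)
    if len(taxa) < 3:
        raise ConfigError("need at least 3 shared taxa")
    if len(visual.dates) < 2 or len(reads.dates) < 2:
        raise ConfigError("need at least 2 dates per layer")

    g = nx.Graph(threshold=threshold, alpha=alpha)
    nodes = [(d, "visual") for d in visual.dates] + [(d, "eDNA") for d in reads.dates]
    for d, layer in nodes:
        g.add_node((d.strftime("%Y-%m-%d"), layer), date=d.strftime("%Y-%m-%d"), layer=layer)

    def vec(layer: str, d):
        m = visual if layer == "visual" else reads
        return m.values.loc[d, taxa].to_numpy()

    for i, (d1, l1) in enumerate(nodes):
        for d2, l2 in nodes[i + 1 :]:
            if (d1, l1) == (d2, l2):
                continue
            if {l1, l2} == {"eDNA"} and not include_edna_edna:
                continue
            res = loglog_pearson(vec(l1, d1), vec(l2, d2), pseudocount)
            if res.undefined:
                continue
            if res.coefficient >= threshold and res.p_one_tail < alpha and res.coefficient > 0:
                g.add_edge(
                    (d1.strftime("%Y-%m-%d"), l1),
                    (d2.strftime("%Y-%m-%d"), l2),
                    r=res.coefficient,
                    p=res.p_one_tail,
                )
    return g


def network_edge_list(g: nx.Graph) -> pd.DataFrame:
    rows = [
        {
            "date_a": a[0], "layer_a": a[1],
            "date_b": b[0], "layer_b": b[1],
            "r": d["r"], "p": d["p"],
        }
        for a, b, d in g.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["date_a", "layer_a", "date_b", "layer_b", "r", "p"])


def checklist_concordance(
    checklists: pd.DataFrame,
    focal: CommunityMatrix,
    reads: CommunityMatrix,
    min_checklists: int = 3,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Is eDNA as concordant with the focal survey as other observers are?

    For each date carrying at least ``min_checklists`` complete checklists:
    Kendall tau-b between the focal survey and each checklist, with a
    seeded percentile bootstrap (``n_boot`` resamples over checklists) for
    the mean and its 95% CI; Kendall tau-b between standardized reads and
    the focal survey; and whether the eDNA tau exceeds the mean observer
    tau.  Dates with fewer checklists are excluded.
    """
    cl = checklists.copy()
    cl["date"] = pd.to_datetime(cl["date"])
    rng = np.random.default_rng(seed)
    rows = []
    for d in reads.dates:
        if d not in focal.dates:
            continue
        day = cl[cl["date"] == d]
        ids = sorted(day["checklist_id"].unique())
        if len(ids) < min_checklists:
            logger.info("%s: only %d checklists (< %d); excluded", d.date(), len(ids), min_checklists)
            continue
        taxa = _shared_taxa(focal, reads)
        if len(taxa) < 3:
            continue
        focal_vec = focal.values.loc[d, taxa].to_numpy()

        taus = []
        for cid in ids:
            one = day[day["checklist_id"] == cid].set_index("species")["count"]
            vec = np.array([float(one.get(t, 0)) for t in taxa])
            res = kendall_tau(focal_vec, vec)
            taus.append(res.coefficient)
        taus = np.array(taus, dtype=float)
        boot_means = np.array(
            [np.nanmean(taus[rng.integers(len(taus), size=len(taus))]) for _ in range(n_boot)]
        )
        lo, hi = np.nanpercentile(boot_means, [2.5, 97.5])

        edna = kendall_tau(reads.values.loc[d, taxa].to_numpy(), focal_vec)
        mean_tau = float(np.nanmean(taus))
        rows.append(
            {
                "date": d,
                "n_checklists": len(ids),
                "mean_checklist_tau": mean_tau,
                "ci_low": float(lo),
                "ci_high": float(hi),
                "edna_tau": edna.coefficient,
                "edna_p_one_tail": edna.p_one_tail,
                "edna_exceeds_mean": bool(edna.coefficient > mean_tau),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "date", "n_checklists", "mean_checklist_tau", "ci_low", "ci_high",
            "edna_tau", "edna_p_one_tail", "edna_exceeds_mean",
        ],
    )
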