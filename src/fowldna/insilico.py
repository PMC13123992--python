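"""Mismatch-tolerant in-silico PCR of degenerate primer pairs.

Given a primer pair and a reference sequence, :func:`find_amplicons` locates
every site where the forward primer binds with at most ``max_mismatch``
set-intersection mismatches and pairs it with downstream reverse-primer
sites, on both strands.  :func:`run_insilico_pcr` applies this scan to a
whole reference set and summarises which taxa each pair amplifies,
including the percentage of target-family species among everything
amplified — the specificity statistic used to evaluate tribe-targeted
waterfowl primers against a mixed vertebrate database.

Conventions (stated once, used everywhere):

* coordinates are 0-based half-open on the plus strand;
* the amplicon includes both primer footprints, so its length equals
  insert + len(forward) + len(reverse);
* the mismatch budget applies to each primer separately, not summed;
* when one forward site could pair with several reverse sites, the
  shortest legal product is reported (dominant short-product kinetics),
  and candidates nested inside a reported product are suppressed;
* a minus-strand hit is reported in plus-strand coordinates with
  ``strand='-'`` and ``amplicon_seq`` giving the minus-strand product.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .primers import PrimerPair, iupac_to_bits, reverse_complement

__all__ = [
    "AmpliconHit",
    "SpecificityReport",
    "scan_primer_sites",
    "find_amplicons",
    "run_insilico_pcr",
]

logger = logging.getLogger(__name__)

DEFAULT_MAX_MISMATCH = 2


@dataclass(frozen=True)
class AmpliconHit:
    """One predicted PCR product on a reference record."""

    record_id: str
    strand: str  # '+' or '-'
    start: int  # 0-based inclusive, plus-strand coordinates
    end: int  # 0-based exclusive
    fwd_mismatches: int
    rev_mismatches: int
    amplicon_seq: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.end - self.start != len(self.amplicon_seq):
            raise ValueError("amplicon_seq length does not match coordinates")

    def __len__(self) -> int:
        return self.end - self.start


def scan_primer_sites(primer: str, sequence: str, max_mismatch: int) -> dict[int, int]:
    """Map start offset -> mismatch count for every window within budget.

    Vectorised over all windows: both primer and template are encoded as
    IUPAC bitmasks and a position matches when the masks intersect.
    """
    p = iupac_to_bits(primer)
    s = iupac_to_bits(sequence)
    k = len(p)
    if len(s) < k:
        return {}
    windows = np.lib.stride_tricks.sliding_window_view(s, k)
    mismatches = ((windows & p) == 0).sum(axis=1)
    keep = np.flatnonzero(mismatches <= max_mismatch)
    return {int(i): int(mismatches[i]) for i in keep}


def _pair_sites(
    fwd_sites: dict[int, int],
    rev_sites: dict[int, int],
    fwd_len: int,
    rev_len: int,
    max_amplicon: int,
) -> list[tuple[int, int, int, int]]:
    """Pair forward sites with downstream reverse sites.

    Returns (start, end, fwd_mm, rev_mm) tuples: per forward site the
    shortest legal product, with candidates nested inside another candidate
    suppressed.
    """
    rev_starts = sorted(rev_sites)
    candidates: list[tuple[int, int, int, int]] = []
    for s in sorted(fwd_sites):
        for r in rev_starts:
            if r < s + fwd_len:
                continue  # primers may not overlap
            end = r + rev_len
            if end - s > max_amplicon:
                break
            candidates.append((s, end, fwd_sites[s], rev_sites[r]))
            break  # shortest product for this forward site
    kept = [
        c
        for c in candidates
        if not any(
            (o[0] <= c[0] and c[1] <= o[1] and (o[0], o[1]) != (c[0], c[1]))
            for o in candidates
        )
    ]
    return kept


def find_amplicons(
    pair: PrimerPair,
    record: str,
    record_id: str = "",
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    max_amplicon: int | None = None,
) -> list[AmpliconHit]:
    """Predict PCR products of ``pair`` on a reference sequence.

    Scans the plus strand for forward-primer sites and, downstream of each,
    for sites matching the reverse complement of the reverse primer; then
    repeats with roles swapped for minus-strand products.  Hits are sorted
    by (start, end).

    Parameters
    ----------
    pair
        The primer pair to scan with.
    record
        Reference sequence (IUPAC codes tolerated).
    record_id
        Identifier carried into the hits.
    max_mismatch
        Per-primer mismatch budget (default 2).
    max_amplicon
        Longest product to report; defaults to twice the pair's expected
        amplicon size (or 4x the summed primer lengths if no expectation
        is set).
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    flen, rlen = len(pair.forward), len(pair.reverse)
    if max_amplicon is None:
        max_amplicon = (
            2 * pair.expected_amplicon if pair.expected_amplicon else 4 * (flen + rlen)
        )
    if max_amplicon <= flen + rlen:
        raise ValueError("max_amplicon must exceed the summed primer lengths")

    seq = record.upper()
    L = len(seq)
    hits: list[AmpliconHit] = []

    # Plus strand: forward primer 5'->3' on plus; reverse primer binds the
    # minus strand, i.e. its reverse complement appears on the plus strand.
    fwd = scan_primer_sites(pair.forward, seq, max_mismatch)
    rev = scan_primer_sites(reverse_complement(pair.reverse), seq, max_mismatch)
    for start, end, fmm, rmm in _pair_sites(fwd, rev, flen, rlen, max_amplicon):
        hits.append(
            AmpliconHit(record_id, "+", start, end, fmm, rmm, seq[start:end])
        )

    # Minus strand: run the same logic on the reverse complement and map
    # coordinates back (position i on the rc is L - i on the plus strand).
    rc = reverse_complement(seq)
    fwd_m = scan_primer_sites(pair.forward, rc, max_mismatch)
    rev_m = scan_primer_sites(reverse_complement(pair.reverse), rc, max_mismatch)
    for s, e, fmm, rmm in _pair_sites(fwd_m, rev_m, flen, rlen, max_amplicon):
        hits.append(
            AmpliconHit(record_id, "-", L - e, L - s, fmm, rmm, rc[s:e])
        )

    hits.sort(key=lambda h: (h.start, h.end, h.strand))
    return hits


@dataclass
class SpecificityReport:
    """Which taxa a primer set amplifies, and how target-specific it is.

    ``pct_target`` is 100 x target species / (target + non-target species),
    the statistic used to judge whether tribe-targeted primers amplify
    waterfowl preferentially over other vertebrates.
    """

    target_family: str
    target_species_amplified: int = 0
    nontarget_species_amplified: int = 0
    species_by_family: dict[str, int] = field(default_factory=dict)
    species_by_class: dict[str, int] = field(default_factory=dict)
    records_by_family: dict[str, int] = field(default_factory=dict)

    @property
    def pct_target(self) -> float:
        denom = self.target_species_amplified + self.nontarget_species_amplified
        return 100.0 * self.target_species_amplified / denom if denom else 0.0

    def summary(self) -> str:
        lines = [
            f"target family: {self.target_family}",
            f"target species amplified: {self.target_species_amplified}",
            f"non-target species amplified: {self.nontarget_species_amplified}",
            f"percent target: {self.pct_target:.1f}%",
            "species per class: "
            + ", ".join(f"{k}={v}" for k, v in sorted(self.species_by_class.items())),
            "species per family: "
            + ", ".join(f"{k}={v}" for k, v in sorted(self.species_by_family.items())),
        ]
        return "\n".join(lines)


def run_insilico_pcr(
    pairs: list[PrimerPair] | tuple[PrimerPair, ...],
    references: dict[str, str],
    lineage: pd.DataFrame,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    target_family: str = "Anatidae",
) -> tuple[pd.DataFrame, SpecificityReport]:
    """Scan every reference with every pair and summarise amplified taxa.

    Parameters
    ----------
    pairs
        Primer pairs to evaluate.
    references
        Mapping record id -> sequence.
    lineage
        One row per record: columns ``record_id species genus family tribe
        class`` (``tribe`` optional).  Records without a lineage row are
        counted under "unclassified" with a warning.
    max_mismatch
        Per-primer mismatch budget.
    target_family
        Family counted as on-target in the specificity report.

    Returns
    -------
    (table, report)
        ``table`` has one row per (pair, record) with at least one hit,
        carrying the best hit (fewest total mismatches, then shortest).
    """
    lin = lineage.set_index("record_id")
    rows = []
    amplified_species: set[tuple[str, str, str]] = set()
    records_by_family: dict[str, int] = defaultdict(int)

    for rid, seq in references.items():
        if rid in lin.index:
            species = str(lin.at[rid, "species"])
            family = str(lin.at[rid, "family"])
            klass = str(lin.at[rid, "class"])
        else:
            logger.warning("record %s missing from lineage table; counted as unclassified", rid)
            species, family, klass = rid, "unclassified", "unclassified"
        record_amplified = False
        for pair in pairs:
            hits = find_amplicons(pair, seq, rid, max_mismatch=max_mismatch)
            if not hits:
                continue
            record_amplified = True
            best = min(
                hits, key=lambda h: (h.fwd_mismatches + h.rev_mismatches, len(h))
            )
            rows.append(
                {
                    "pair": pair.name,
                    "record_id": rid,
                    "species": species,
                    "family": family,
                    "class": klass,
                    "strand": best.strand,
                    "start": best.start,
                    "end": best.end,
                    "fwd_mm": best.fwd_mismatches,
                    "rev_mm": best.rev_mismatches,
                    "amplicon_len": len(best),
                }
            )
            amplified_species.add((species, family, klass))
        if record_amplified:
            records_by_family[family] += 1

    columns = [
        "pair", "record_id", "species", "family", "class",
        "strand", "start", "end", "fwd_mm", "rev_mm", "amplicon_len",
    ]
    table = pd.DataFrame(rows, columns=columns)

    report = SpecificityReport(target_family=target_family)
    by_family: dict[str, set[str]] = defaultdict(set)
    by_class: dict[str, set[str]] = defaultdict(set)
    for species, family, klass in amplified_species:
        by_family[family].add(species)
        by_class[klass].add(species)
        if family == target_family:
            report.target_species_amplified += 1
        else:
            report.nontarget_species_amplified += 1
    report.species_by_family = {k: len(v) for k, v in by_family.items()}
    report.species_by_class = {k: len(v) for k, v in by_class.items()}
    report.records_by_family = dict(records_by_family)
    return table, report
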