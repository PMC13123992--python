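"""Synthetic waterfowl-migration eDNA study with known ground truth.

Emulates every input of the analysis pipeline so each downstream stage can
be tested against truth: Gaussian migration passage curves per species,
negative-binomial visual surveys and community checklists, reference ND2
sequences carrying the tribe-matched primer sites, Dirichlet-multinomial
amplicon read tables with negative controls and contamination, and
BLAST-style hit tables with configurable distractors.

The default configuration mirrors the study system the pipeline was built
for: ten weekly sampling dates across a fall migration (late September to
late November), three field replicates plus one field blank per date,
dabbling ducks peaking early and diving ducks late, species peak abundances
spanning several orders of magnitude, and a per-sample read depth of
650,000.

All randomness flows from one root seed through fixed named substreams, so
each operation is independently reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date as Date
from datetime import timedelta

import numpy as np
import pandas as pd

from .containers import AsvTable, CommunityMatrix, ConfigError
from .insilico import find_amplicons
from .primers import (
    DEFAULT_PRIMER_PAIRS,
    PRIMER_PAIR_BY_TARGET,
    PrimerPair,
    expand_degenerate,
    reverse_complement,
)

__all__ = [
    "TRIBE_GROUPS",
    "SpeciesParams",
    "SimulationConfig",
    "default_species",
    "default_config",
    "simulate_abundance",
    "simulate_surveys",
    "simulate_references",
    "simulate_reads",
    "simulate_all",
    "SurveyData",
    "ReferenceSet",
    "ReadSimulation",
]

#: The three primer target groups; every species belongs to exactly one,
#: which decides whose primer sites its reference sequence carries.
TRIBE_GROUPS = tuple(p.target_group for p in DEFAULT_PRIMER_PAIRS)

# Substream indices: every operation draws from its own child of the root
# seed, so re-running one stage never perturbs another.
_STREAMS = {
    "surveys": 1,
    "references": 2,
    "reads": 3,
    "asv_split": 4,
    "hits": 5,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


@dataclass(frozen=True)
class SpeciesParams:
    """Migration-passage and eDNA-shedding parameters of one species.

    ``peak_date``/``passage_width`` place a Gaussian pulse of abundance in
    the season; ``shedding_factor`` scales the species' expected read
    contribution per individual.
    """

    species_name: str
    tribe: str
    peak_date: Date
    passage_width: float  # days
    peak_abundance: float  # individuals at the peak
    shedding_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.tribe not in TRIBE_GROUPS:
            raise ConfigError(f"unknown tribe group {self.tribe!r}; expected one of {TRIBE_GROUPS}")
        if self.passage_width <= 0:
            raise ConfigError("passage_width must be > 0")
        if self.peak_abundance < 0:
            raise ConfigError("peak_abundance must be >= 0")
        if self.shedding_factor <= 0:
            raise ConfigError("shedding_factor must be > 0")

    @property
    def genus(self) -> str:
        return self.species_name.split()[0]


@dataclass(frozen=True)
class SimulationConfig:
    """Everything the generator needs, validated on construction."""

    seed: int
    dates: tuple[Date, ...]
    species: tuple[SpeciesParams, ...]
    detection_prob: float = 0.9
    observer_dispersion: float = 0.1
    read_depth_per_sample: int = 650_000
    read_overdispersion: float = 0.05
    lag_kernel: tuple[float, ...] = (0.40, 0.25, 0.15, 0.10, 0.06, 0.04)
    contamination_rate: float = 0.02
    n_field_replicates: int = 3
    n_negatives: int = 2
    # generator knobs beyond the core study parameters
    n_checklists_per_date: int = 3
    n_asvs_per_species: int = 2
    n_decoys: int = 5
    flank_length: int = 100
    p_tied_congener: float = 0.0
    p_sub98: float = 0.0
    p_unclassifiable: float = 0.0
    decoy_max_attempts: int = 200

    def __post_init__(self) -> None:
        if not self.dates:
            raise ConfigError("dates must be non-empty")
        if not self.species:
            raise ConfigError("species list must be non-empty")
        if list(self.dates) != sorted(set(self.dates)):
            raise ConfigError("dates must be strictly increasing")
        if not (0 < self.detection_prob <= 1):
            raise ConfigError("detection_prob must be in (0, 1]")
        if self.observer_dispersion < 0 or self.read_overdispersion < 0:
            raise ConfigError("dispersions must be >= 0")
        if self.read_depth_per_sample <= 0:
            raise ConfigError("read_depth_per_sample must be > 0")
        if len(self.lag_kernel) != 6:
            raise ConfigError("lag_kernel must have exactly 6 weights (lags 0..5 days)")
        if any(w < 0 for w in self.lag_kernel):
            raise ConfigError("lag_kernel weights must be >= 0")
        if abs(sum(self.lag_kernel) - 1.0) > 1e-9:
            raise ConfigError("lag_kernel weights must sum to 1")
        if not (0 <= self.contamination_rate < 1):
            raise ConfigError("contamination_rate must be in [0, 1)")
        if self.n_field_replicates < 1 or self.n_negatives < 1:
            raise ConfigError("n_field_replicates and n_negatives must be >= 1")
        for p in (self.p_tied_congener, self.p_sub98, self.p_unclassifiable):
            if not (0 <= p <= 1):
                raise ConfigError("distractor probabilities must be in [0, 1]")


def default_species() -> tuple[SpeciesParams, ...]:
    """A fall-migration waterfowl roster.

    Dabbling ducks (Anatini group) peak early to mid season, geese and
    swans span the season, diving ducks and mergansers (Aythyini/Mergini)
    peak late — the turnover a migration stopover shows.  Peak abundances
    run from a handful of individuals to several thousand.
    """
    d = Date
    return (
        SpeciesParams("Anas platyrhynchos", "Anatini/Cairinini/Oxyura", d(2020, 10, 5), 18.0, 3000),
        SpeciesParams("Anas acuta", "Anatini/Cairinini/Oxyura", d(2020, 10, 1), 12.0, 800),
        SpeciesParams("Anas crecca", "Anatini/Cairinini/Oxyura", d(2020, 10, 10), 14.0, 1500),
        SpeciesParams("Spatula discors", "Anatini/Cairinini/Oxyura", d(2020, 9, 28), 8.0, 400),
        SpeciesParams("Mareca strepera", "Anatini/Cairinini/Oxyura", d(2020, 10, 15), 15.0, 250),
        SpeciesParams("Aix sponsa", "Anatini/Cairinini/Oxyura", d(2020, 9, 30), 10.0, 60),
        SpeciesParams("Oxyura jamaicensis", "Anatini/Cairinini/Oxyura", d(2020, 11, 1), 16.0, 120),
        SpeciesParams("Branta canadensis", "Anserini/Cygnini", d(2020, 10, 20), 30.0, 5000),
        SpeciesParams("Anser caerulescens", "Anserini/Cygnini", d(2020, 11, 10), 12.0, 2000),
        SpeciesParams("Anser rossii", "Anserini/Cygnini", d(2020, 11, 12), 10.0, 8),
        SpeciesParams("Cygnus columbianus", "Anserini/Cygnini", d(2020, 11, 15), 12.0, 300),
        SpeciesParams("Aythya collaris", "Aythyini/Mergini", d(2020, 11, 5), 14.0, 1200),
        SpeciesParams("Aythya valisineria", "Aythyini/Mergini", d(2020, 11, 12), 10.0, 500),
        SpeciesParams("Aythya americana", "Aythyini/Mergini", d(2020, 11, 8), 12.0, 150),
        SpeciesParams("Bucephala albeola", "Aythyini/Mergini", d(2020, 11, 18), 9.0, 90),
        SpeciesParams("Lophodytes cucullatus", "Aythyini/Mergini", d(2020, 11, 20), 10.0, 25),
    )


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Ten weekly sampling dates (late Sep – late Nov) with the default roster."""
    start = Date(2020, 9, 24)
    dates = tuple(start + timedelta(days=7 * k) for k in range(10))
    cfg = SimulationConfig(seed=seed, dates=dates, species=default_species())
    return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# abundance

def _abundance_value(sp: SpeciesParams, day: Date) -> int:
    dt = (day - sp.peak_date).days
    return int(round(sp.peak_abundance * math.exp(-(dt * dt) / (2.0 * sp.passage_width**2))))


def simulate_abundance(
    config: SimulationConfig, dates: tuple[Date, ...] | None = None
) -> CommunityMatrix:
    """True individuals present per (date, species): a deterministic
    Gaussian passage curve ``round(peak * exp(-(t - peak_date)^2 / (2 w^2)))``.

    ``dates`` defaults to the configured sampling dates; passing a denser
    grid evaluates the same curves on it (used for daily checklists and
    lagged read generation).
    """
    dates = tuple(dates) if dates is not None else config.dates
    if not dates:
        raise ConfigError("dates must be non-empty")
    values = pd.DataFrame(
        {
            sp.species_name: [_abundance_value(sp, d) for d in dates]
            for sp in config.species
        },
        index=pd.to_datetime(list(dates)),
    )
    return CommunityMatrix(values, provenance="truth")


def daily_dates(config: SimulationConfig, lookback: int = 5) -> tuple[Date, ...]:
    """Every calendar day from ``lookback`` days before the first sampling
    date through the last one."""
    start = min(config.dates) - timedelta(days=lookback)
    end = max(config.dates)
    return tuple(start + timedelta(days=k) for k in range((end - start).days + 1))


# ---------------------------------------------------------------------------
# surveys

@dataclass
class SurveyData:
    """Observed focal surveys and community checklists, plus the truth used."""

    focal: pd.DataFrame  # date species count (one exhaustive survey per sampling date)
    checklists: pd.DataFrame  # checklist_id date species count (daily)
    truth: CommunityMatrix


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with var = m + dispersion * m^2 (Poisson at 0)."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if not pos.any():
        return out
    if dispersion == 0:
        out[pos] = rng.poisson(mean[pos])
    else:
        r = 1.0 / dispersion
        p = r / (r + mean[pos])
        out[pos] = rng.negative_binomial(r, p)
    return out


def simulate_surveys(truth: CommunityMatrix, config: SimulationConfig) -> SurveyData:
    """Draw observer counts from the true abundances.

    One exhaustive focal survey is taken on each sampling date; community
    checklists (``n_checklists_per_date`` of them) are filed every calendar
    day from five days before the first sampling date onward, so lagged
    analyses have daily survey coverage.  Each observer's count for a
    species is negative-binomial with mean ``detection_prob * abundance``.
    """
    rng = _rng(config.seed, "surveys")
    species = [sp.species_name for sp in config.species]

    focal_rows = []
    for d in config.dates:
        truth_row = truth.values.loc[pd.Timestamp(d)]
        counts = _nb_counts(
            rng, config.detection_prob * truth_row.to_numpy(), config.observer_dispersion
        )
        for s, c in zip(species, counts):
            focal_rows.append({"date": pd.Timestamp(d), "species": s, "count": int(c)})
    focal = pd.DataFrame(focal_rows, columns=["date", "species", "count"])

    days = daily_dates(config)
    daily_truth = simulate_abundance(config, days)
    cl_rows = []
    k = 0
    for d in days:
        truth_row = daily_truth.values.loc[pd.Timestamp(d)].to_numpy()
        for _ in range(config.n_checklists_per_date):
            k += 1
            cid = f"CL{k:05d}"
            counts = _nb_counts(
                rng, config.detection_prob * truth_row, config.observer_dispersion
            )
            for s, c in zip(species, counts):
                cl_rows.append(
                    {"checklist_id": cid, "date": pd.Timestamp(d), "species": s, "count": int(c)}
                )
    checklists = pd.DataFrame(cl_rows, columns=["checklist_id", "date", "species", "count"])
    return SurveyData(focal=focal, checklists=checklists, truth=truth)


# ---------------------------------------------------------------------------
# references

@dataclass
class ReferenceSet:
    """Reference sequences with their taxonomic lineages."""

    records: dict[str, str]  # record_id -> sequence
    lineage: pd.DataFrame  # record_id species genus family tribe class

    def write_fasta(self, path) -> None:
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        recs = [
            SeqRecord(Seq(seq), id=rid, description="")
            for rid, seq in self.records.items()
        ]
        SeqIO.write(recs, path, "fasta")

    @classmethod
    def read(cls, fasta_path, lineage_path) -> "ReferenceSet":
        from Bio import SeqIO

        records = {
            rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")
        }
        lineage = pd.read_csv(lineage_path, sep="\t")
        return cls(records=records, lineage=lineage)


_DECOY_POOL = (
    # non-target vertebrates a mixed water sample could contain
    ("Esox lucius", "Esox", "Esocidae", "", "Actinopterygii"),
    ("Micropterus salmoides", "Micropterus", "Centrarchidae", "", "Actinopterygii"),
    ("Perca flavescens", "Perca", "Percidae", "", "Actinopterygii"),
    ("Ondatra zibethicus", "Ondatra", "Cricetidae", "", "Mammalia"),
    ("Castor canadensis", "Castor", "Castoridae", "", "Mammalia"),
    ("Homo sapiens", "Homo", "Hominidae", "", "Mammalia"),
    ("Lithobates catesbeianus", "Lithobates", "Ranidae", "", "Amphibia"),
    ("Chelydra serpentina", "Chelydra", "Chelydridae", "", "Reptilia"),
)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _concrete(rng: np.random.Generator, primer: str) -> str:
    """Resolve degenerate positions uniformly at random."""
    options = sorted(expand_degenerate(primer))
    return options[rng.integers(len(options))]


def simulate_references(config: SimulationConfig) -> ReferenceSet:
    """Build the reference database the taxonomy/in-silico stages run on.

    Each species gets one record whose sequence embeds, for its tribe's
    primer pair, an exact forward-primer site, an insert of the pair's
    expected length, and the reverse complement of the reverse-primer site,
    framed by random flanks.  Degenerate primer positions are resolved
    uniformly at random, so references exercise the set-matching rule.
    Decoy (fish/mammal/amphibian/reptile) records are rejection-sampled to
    carry no primer site within 2 mismatches for any pair.
    """
    rng = _rng(config.seed, "references")
    records: dict[str, str] = {}
    rows = []

    for i, sp in enumerate(config.species):
        pair = PRIMER_PAIR_BY_TARGET[sp.tribe]
        seq = (
            _random_seq(rng, config.flank_length)
            + _concrete(rng, pair.forward)
            + _random_seq(rng, pair.expected_insert)
            + reverse_complement(_concrete(rng, pair.reverse))
            + _random_seq(rng, config.flank_length)
        )
        rid = f"REF{i + 1:03d}"
        records[rid] = seq
        rows.append(
            {
                "record_id": rid,
                "species": sp.species_name,
                "genus": sp.genus,
                "family": "Anatidae",
                "tribe": sp.tribe,
                "class": "Aves",
            }
        )

    decoy_len = config.flank_length * 2 + 350
    for j in range(config.n_decoys):
        name, genus, family, tribe, klass = _DECOY_POOL[j % len(_DECOY_POOL)]
        for attempt in range(config.decoy_max_attempts):
            seq = _random_seq(rng, decoy_len)
            if not any(
                find_amplicons(pair, seq, max_mismatch=2) for pair in DEFAULT_PRIMER_PAIRS
            ):
                break
        else:
            raise RuntimeError(
                f"could not generate a primer-free decoy in {config.decoy_max_attempts} attempts"
            )
        rid = f"DEC{j + 1:03d}"
        records[rid] = seq
        rows.append(
            {
                "record_id": rid,
                "species": name,
                "genus": genus,
                "family": family,
                "tribe": tribe,
                "class": klass,
            }
        )

    lineage = pd.DataFrame(rows, columns=["record_id", "species", "genus", "family", "tribe", "class"])
    return ReferenceSet(records=records, lineage=lineage)


# ---------------------------------------------------------------------------
# reads

@dataclass
class ReadSimulation:
    """Simulated ASV read table with its ground truth and hit table."""

    asv_table: AsvTable
    asv_truth: pd.DataFrame  # asv_id -> true species
    hits: pd.DataFrame  # asv_id subject_species subject_genus subject_family pct_identity score


def lagged_expected_shares(
    config: SimulationConfig, sampling_date: Date
) -> pd.Series:
    """Expected read share per species on a sampling date.

    Share(s) is proportional to ``shedding_factor_s * sum_l kernel[l] *
    abundance(t - l, s)``: eDNA integrates recent presence over the 0–5 day
    look-back with the configured kernel weights.
    """
    weights = {}
    for sp in config.species:
        acc = 0.0
        for lag, w in enumerate(config.lag_kernel):
            acc += w * _abundance_value(sp, sampling_date - timedelta(days=lag))
        weights[sp.species_name] = sp.shedding_factor * acc
    w = pd.Series(weights, dtype=float)
    total = w.sum()
    if total <= 0:
        # nothing present in the look-back window: uniform over species
        return pd.Series(1.0 / len(w), index=w.index)
    return w / total


def simulate_reads(
    truth: CommunityMatrix, config: SimulationConfig
) -> ReadSimulation:
    """Draw the ASV x sample read table, controls, and the BLAST-style hit table.

    Field samples are Dirichlet-multinomial draws of ``read_depth_per_sample``
    reads over ASVs; each species carries ``n_asvs_per_species`` ASVs with a
    fixed within-species haplotype split.  Every blank (field, filtration,
    extraction, PCR) receives sparse contamination: each ASV independently
    present with probability ``contamination_rate`` at small geometric
    counts.  The hit table assigns each ASV its true lineage at >= 98%
    identity, with optional distractors (tied congeners, sub-98% identity,
    cross-family ties) to exercise every assignment branch.
    """
    sampled = {pd.Timestamp(d) for d in config.dates}
    missing = sampled - set(truth.values.index)
    if missing:
        raise ConfigError(f"truth matrix lacks sampling dates: {sorted(missing)}")

    rng = _rng(config.seed, "reads")
    split_rng = _rng(config.seed, "asv_split")
    species = [sp.species_name for sp in config.species]

    # Stable ASV roster: k haplotypes per species with a fixed frequency split.
    asv_ids: list[str] = []
    asv_species: list[str] = []
    asv_frac: list[float] = []
    k = config.n_asvs_per_species
    for i, name in enumerate(species):
        split = (
            np.ones(1) if k == 1 else split_rng.dirichlet(np.full(k, 5.0))
        )
        for j in range(k):
            asv_ids.append(f"ASV{i * k + j + 1:04d}")
            asv_species.append(name)
            asv_frac.append(float(split[j]))
    asv_frac_arr = np.array(asv_frac)
    species_index = {name: np.flatnonzero(np.array(asv_species) == name) for name in species}

    # Sample roster.
    sample_ids: list[str] = []
    meta_rows = []
    for d in config.dates:
        iso = d.isoformat()
        for r in range(1, config.n_field_replicates + 1):
            sid = f"F{iso}r{r}"
            sample_ids.append(sid)
            meta_rows.append((sid, pd.Timestamp(d), "field", r))
        sid = f"FB{iso}"
        sample_ids.append(sid)
        meta_rows.append((sid, pd.Timestamp(d), "field_blank", 1))
    last = pd.Timestamp(max(config.dates))
    for btype, prefix in (
        ("filtration_blank", "FILTB"),
        ("extraction_blank", "EXTB"),
        ("pcr_blank", "PCRB"),
    ):
        for r in range(1, config.n_negatives + 1):
            sid = f"{prefix}{r}"
            sample_ids.append(sid)
            meta_rows.append((sid, last, btype, r))

    counts = np.zeros((len(asv_ids), len(sample_ids)), dtype=np.int64)
    col = {s: j for j, s in enumerate(sample_ids)}

    for d in config.dates:
        shares = lagged_expected_shares(config, d)
        p_asv = np.zeros(len(asv_ids))
        for name in species:
            idx = species_index[name]
            block = asv_frac_arr[idx]
            p_asv[idx] = shares[name] * block / block.sum()
        p_asv = p_asv / p_asv.sum()
        for r in range(1, config.n_field_replicates + 1):
            if config.read_overdispersion > 0:
                alpha = p_asv / config.read_overdispersion
                # Dirichlet needs strictly positive alpha; zero-share ASVs stay zero
                pos = alpha > 0
                p_draw = np.zeros_like(p_asv)
                p_draw[pos] = rng.dirichlet(alpha[pos])
            else:
                p_draw = p_asv
            counts[:, col[f"F{d.isoformat()}r{r}"]] = rng.multinomial(
                config.read_depth_per_sample, p_draw
            )

    # Contamination in every blank type.
    if config.contamination_rate > 0:
        for sid, _, stype, _ in meta_rows:
            if stype == "field":
                continue
            present = rng.random(len(asv_ids)) < config.contamination_rate
            n_present = int(present.sum())
            if n_present:
                counts[present, col[sid]] = rng.geometric(0.5, size=n_present)

    asv_table = AsvTable(
        counts=pd.DataFrame(counts, index=asv_ids, columns=sample_ids),
        meta=pd.DataFrame(
            meta_rows, columns=["sample_id", "date", "sample_type", "replicate"]
        ).set_index("sample_id"),
    )
    asv_truth = pd.DataFrame({"asv_id": asv_ids, "species": asv_species}).set_index("asv_id")
    hits = _simulate_hits(config, asv_ids, asv_species)
    return ReadSimulation(asv_table=asv_table, asv_truth=asv_truth, hits=hits)


def _simulate_hits(
    config: SimulationConfig, asv_ids: list[str], asv_species: list[str]
) -> pd.DataFrame:
    """BLAST-tabular-style hit table: true lineage at >= 98% identity plus
    configurable distractor branches."""
    rng = _rng(config.seed, "hits")
    by_genus: dict[str, list[SpeciesParams]] = {}
    params = {sp.species_name: sp for sp in config.species}
    for sp in config.species:
        by_genus.setdefault(sp.genus, []).append(sp)

    rows = []
    for aid, name in zip(asv_ids, asv_species):
        sp = params[name]
        u = rng.random()
        if u < config.p_unclassifiable:
            # equal-identity hits across two families: unresolvable below family
            ident = round(float(rng.uniform(90, 97)), 2)
            rows.append((aid, name, sp.genus, "Anatidae", ident, 400.0))
            rows.append((aid, "Esox lucius", "Esox", "Esocidae", ident, 400.0))
            continue
        if u < config.p_unclassifiable + config.p_sub98:
            # best identity below the species-level threshold
            ident = round(float(rng.uniform(94, 97.9)), 2)
            rows.append((aid, name, sp.genus, "Anatidae", ident, 420.0))
            rows.append((aid, name, sp.genus, "Anatidae", round(ident - 1.5, 2), 400.0))
            continue
        ident = round(float(rng.uniform(98.5, 100.0)), 2)
        rows.append((aid, name, sp.genus, "Anatidae", ident, 450.0))
        if rng.random() < config.p_tied_congener:
            congeners = [s for s in by_genus[sp.genus] if s.species_name != name]
            other = (
                congeners[rng.integers(len(congeners))].species_name
                if congeners
                else f"{sp.genus} cognatus"
            )
            rows.append((aid, other, sp.genus, "Anatidae", ident, 450.0))
        # trailing lower-identity filler hits (never reach the top tie)
        n_filler = int(rng.integers(1, 4))
        for _ in range(n_filler):
            other = config.species[rng.integers(len(config.species))]
            rows.append(
                (
                    aid,
                    other.species_name,
                    other.genus,
                    "Anatidae",
                    round(float(rng.uniform(85, ident - 2.0)), 2),
                    float(rng.uniform(200, 380)),
                )
            )
    return pd.DataFrame(
        rows,
        columns=["asv_id", "subject_species", "subject_genus", "subject_family", "pct_identity", "score"],
    )


# ---------------------------------------------------------------------------
# one-call convenience

@dataclass
class SimulationBundle:
    truth: CommunityMatrix
    surveys: SurveyData
    references: ReferenceSet
    reads: ReadSimulation
    config: SimulationConfig


def simulate_all(config: SimulationConfig) -> SimulationBundle:
    """Run every generator stage from one config."""
    truth = simulate_abundance(config)
    return SimulationBundle(
        truth=truth,
        surveys=simulate_surveys(truth, config),
        references=simulate_references(config),
        reads=simulate_reads(truth, config),
        config=config,
    )
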