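"""Synthetic catchment generator.

Emulates the statistical structure of a two-stream-plus-lake trout system so
that every downstream estimator can be validated offline against known
truth:

* two stream demes diverged from a common ancestral gene pool under the
  F-model (deme allele frequencies Dirichlet-distributed around ancestral
  frequencies with drift parameter F), producing the weak differentiation
  regime (pairwise theta of order 0.001-0.03);
* strongly asymmetric migration: with probability m a family spawning in
  the recipient stream is founded by a straying pair from the source deme,
  so its offspring are first-generation migrants in the sense of the
  migrant-indicator model, and the realized migrant fraction is recorded;
* polygamous matings: sires and dams can each found several families, and
  (at a rate tied to the migration rate) a parent spawns in both streams in
  one season, generating mixed-site half-sibling dyads;
* a lake pool of older fish drawn from both streams' offspring (the lake is
  feeding, not nursery, habitat);
* PIT-antenna detections concentrated in the 1 Nov - 28 Feb spawning
  window, biased to night hours, with per-pass Bernoulli detection;
* tag/recapture growth records following the degree-day growth law with
  Gaussian measurement noise, on a sinusoidal-plus-noise daily temperature
  series.

All randomness flows from one seeded generator; the same seed yields a
byte-identical dataset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import date, datetime, time, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .growthgdd import GrowthObservation, TemperatureSeries, degree_days
from .pitclass import AntennaSite, SpawningWindow, INFLOW, OUTFLOW_UPPER, OUTFLOW_LOWER
from .popgenstats import GenotypeTable, write_genepop

STREAMS = ("inflow", "outflow")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Study-condition defaults for the synthetic catchment.

    Migration defaults mirror the strongly asymmetric regime (about 30% of
    the outflow deriving from the inflow per generation versus about 1% in
    the reverse direction); sample sizes mirror the pooled juvenile groups
    (146 inflow, 124 upper outflow) with a scaled-down lake pool; the
    growth-law coefficients are those of the fitted degree-day equation.
    """

    n_loci: int = 14
    alleles_per_locus: int = 10
    base_freq_concentration: float = 1.0
    divergence_f: float = 0.02
    m_in_to_out: float = 0.30
    m_out_to_in: float = 0.01
    n_families_per_stream: int = 100
    offspring_per_family: dict = field(
        default_factory=lambda: {"kind": "poisson", "mean": 4.0, "min": 1}
    )
    sample_sizes: dict = field(
        default_factory=lambda: {"inflow": 146, "outflow": 124, "lake": 100}
    )
    shared_parent_scale: float = 0.2  # P(shared cross-stream parent) = m * scale
    polygamy_pool_fraction: float = 0.7  # parent pool size / family count
    missing_rate: float = 0.0
    detection_prob_per_pass: float = 0.9
    passes_per_stream_visit: float = 20.0
    behavior_proportions: dict = field(
        default_factory=lambda: {"IO": 39 / 208, "OO": 107 / 208, "B": 62 / 208}
    )
    nocturnality: float = 0.95
    night_start: str = "17:00"
    night_end: str = "08:00"
    temp_mean: float = 10.5
    temp_amplitude: float = 7.5
    temp_winter_floor: float = 4.0
    temp_noise_sd: float = 1.0
    growth_a: float = -0.0303
    growth_b: float = 0.1701
    growth_t0: float = 5.0
    growth_noise_sd: float = 3.0
    n_growth_obs: int = 87
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.divergence_f < 1.0):
            raise ValueError("divergence_f must lie in (0, 1)")
        if self.base_freq_concentration <= 0:
            raise ValueError("base_freq_concentration must be positive")
        for m in (self.m_in_to_out, self.m_out_to_in):
            if not (0.0 <= m <= 1.0 / 3.0):
                raise ValueError("migration rates must lie in [0, 1/3]")
        for name in ("n_loci", "alleles_per_locus", "n_families_per_stream"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive count")
        if not (0.0 <= self.detection_prob_per_pass <= 1.0):
            raise ValueError("detection_prob_per_pass must lie in [0, 1]")
        if any(n <= 0 for n in self.sample_sizes.values()):
            raise ValueError("sample sizes must be positive")


@dataclass
class PedigreeRecord:
    individual: str
    sire: str | None
    dam: str | None
    natal_stream: str | None  # inflow | outflow; None for founder parents
    sire_spawn_streams: tuple[str, ...] = ()
    dam_spawn_streams: tuple[str, ...] = ()
    cohort: int = 0
    migrant_family: bool = False  # both parents derive from the other deme


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genotypes: GenotypeTable
    pedigree: list[PedigreeRecord]
    detections: pd.DataFrame
    behaviors: dict[str, str]  # scripted per-tag behavior class
    captures: list[GrowthObservation]
    temperatures: TemperatureSeries
    truth: dict

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_genepop(self.genotypes, out / "genotypes.gen")
        det = self.detections.copy()
        det["timestamp"] = det["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
        det.to_csv(out / "detections.csv", index=False)
        pd.DataFrame(
            [
                {
                    "tag": o.tag,
                    "fl1": o.fl1,
                    "fl2": o.fl2_obs,
                    "date1": o.date1.isoformat(),
                    "date2": o.date2.isoformat(),
                }
                for o in self.captures
            ]
        ).to_csv(out / "captures.csv", index=False)
        self.temperatures.to_csv(out / "temperatures.csv")
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=2, default=str)


# ---------------------------------------------------------------------------
# allele frequencies (F-model)
# ---------------------------------------------------------------------------

def simulate_allele_frequencies(
    config: SimulationConfig, rng: np.random.Generator
) -> dict[str, list[np.ndarray]]:
    """Ancestral and per-deme allele frequencies under the F-model.

    Per locus, ancestral frequencies are Dirichlet(concentration * 1); each
    deme then drifts independently: Dirichlet(ancestral * (1 - F)/F), whose
    mean is the ancestral vector and whose per-allele variance is
    p(1-p) * F — the standard beta/Dirichlet drift parameterization.
    """
    k = config.alleles_per_locus
    f = config.divergence_f
    scale = (1.0 - f) / f
    ancestral: list[np.ndarray] = []
    demes: dict[str, list[np.ndarray]] = {s: [] for s in STREAMS}
    for _ in range(config.n_loci):
        anc = rng.dirichlet(np.full(k, config.base_freq_concentration))
        anc = np.clip(anc, 1e-9, None)
        anc /= anc.sum()
        ancestral.append(anc)
        for s in STREAMS:
            demes[s].append(rng.dirichlet(anc * scale))
    return {"ancestral": ancestral, **demes}


# ---------------------------------------------------------------------------
# pedigree + genotypes
# ---------------------------------------------------------------------------

def _draw_parent_genotype(
    freqs: list[np.ndarray], rng: np.random.Generator
) -> np.ndarray:
    L = len(freqs)
    geno = np.empty((L, 2), dtype=np.int64)
    for j, p in enumerate(freqs):
        geno[j] = rng.choice(len(p), size=2, p=p) + 1  # allele codes 1..k
    return geno


def _mendelian_offspring(
    sire: np.ndarray, dam: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    L = sire.shape[0]
    pick_s = rng.integers(0, 2, size=L)
    pick_d = rng.integers(0, 2, size=L)
    child = np.empty((L, 2), dtype=np.int64)
    child[:, 0] = sire[np.arange(L), pick_s]
    child[:, 1] = dam[np.arange(L), pick_d]
    return child


def _offspring_count(spec: dict, rng: np.random.Generator) -> int:
    if spec.get("kind", "poisson") != "poisson":
        raise ValueError(f"unknown offspring distribution {spec!r}")
    n = int(rng.poisson(spec.get("mean", 6.0)))
    return max(n, int(spec.get("min", 1)))


def simulate_pedigree_and_genotypes(
    config: SimulationConfig,
    freqs: dict[str, list[np.ndarray]],
    rng: np.random.Generator,
) -> tuple[list[PedigreeRecord], GenotypeTable, dict]:
    """Families, offspring genotypes and the sampled genotype table.

    Families in each stream draw their parents from per-stream polygamy
    pools (pool smaller than the family count, so parents of either sex can
    found several families).  Each offspring born in a stream is,
    independently with probability equal to the incoming migration rate,
    instead the product of a straying pair whose gametes come from the
    source deme (drawn from a small pool of migrant pairs, preserving
    family structure among migrants): such offspring are first-generation
    migrants, and the realized migrant fraction among sampled individuals
    is binomial around the nominal rate.  Separately, with probability
    m * shared_parent_scale a family shares one parent (sire or dam, equal
    odds) with the source stream, so that parent spawns in both streams in
    one season, creating mixed-site half-sib dyads.

    Sampling: per-site sample sizes come from ``config.sample_sizes``; lake
    samples are drawn evenly from both streams' leftover offspring.  Raises
    if any requested sample exceeds the generated offspring.
    """
    for s in STREAMS:
        if not freqs.get(s):
            raise ValueError(f"no allele frequencies for deme {s!r}")
    m_into = {"outflow": config.m_in_to_out, "inflow": config.m_out_to_in}
    source_of = {"outflow": "inflow", "inflow": "outflow"}

    pool_size = max(2, int(round(config.n_families_per_stream * config.polygamy_pool_fraction)))
    parent_geno: dict[str, np.ndarray] = {}
    parent_deme: dict[str, str] = {}
    parent_spawns: dict[str, set[str]] = {}
    pools: dict[str, dict[str, list[str]]] = {}
    for s in STREAMS:
        pools[s] = {"sire": [], "dam": []}
        for sex in ("sire", "dam"):
            for i in range(pool_size):
                pid = f"{s[:3].upper()}_{sex[0].upper()}{i:03d}"
                parent_geno[pid] = _draw_parent_genotype(freqs[s], rng)
                parent_deme[pid] = s
                parent_spawns[pid] = set()
                pools[s][sex].append(pid)

    pedigree: list[PedigreeRecord] = []
    offspring_by_stream: dict[str, list[tuple[str, np.ndarray, bool]]] = {
        s: [] for s in STREAMS
    }
    child_counter = 0

    for stream in STREAMS:
        src = source_of[stream]
        m = m_into[stream]
        p_shared = min(1.0, m * config.shared_parent_scale)
        # migrant pairs: a straying couple from the source deme spawning in
        # this stream; sized so migrant offspring form a few true families
        n_mig_pairs = max(1, int(round(m * config.n_families_per_stream))) if m > 0 else 0
        migrant_pairs = [
            (
                str(rng.choice(pools[src]["sire"])),
                str(rng.choice(pools[src]["dam"])),
            )
            for _ in range(n_mig_pairs)
        ]
        for s, d in migrant_pairs:
            parent_spawns[s].add(stream)
            parent_spawns[d].add(stream)
        for _ in range(config.n_families_per_stream):
            if rng.random() < p_shared:
                # one parent spawns in both streams this season
                if rng.random() < 0.5:
                    sire = str(rng.choice(pools[src]["sire"]))
                    dam = str(rng.choice(pools[stream]["dam"]))
                else:
                    sire = str(rng.choice(pools[stream]["sire"]))
                    dam = str(rng.choice(pools[src]["dam"]))
            else:
                sire = str(rng.choice(pools[stream]["sire"]))
                dam = str(rng.choice(pools[stream]["dam"]))
            parent_spawns[sire].add(stream)
            parent_spawns[dam].add(stream)
            n_off = _offspring_count(config.offspring_per_family, rng)
            for _ in range(n_off):
                child_counter += 1
                cid = f"J{child_counter:05d}"
                # each birth is independently a migrant-pair offspring
                migrant = bool(migrant_pairs) and rng.random() < m
                if migrant:
                    msire, mdam = migrant_pairs[int(rng.integers(0, n_mig_pairs))]
                    geno = _mendelian_offspring(
                        parent_geno[msire], parent_geno[mdam], rng
                    )
                    rec_sire, rec_dam = msire, mdam
                else:
                    geno = _mendelian_offspring(
                        parent_geno[sire], parent_geno[dam], rng
                    )
                    rec_sire, rec_dam = sire, dam
                offspring_by_stream[stream].append((cid, geno, migrant))
                pedigree.append(
                    PedigreeRecord(
                        individual=cid,
                        sire=rec_sire,
                        dam=rec_dam,
                        natal_stream=stream,
                        cohort=1,
                        migrant_family=migrant,
                    )
                )

    # freeze each parent's realized spawning streams into the records
    for rec in pedigree:
        rec.sire_spawn_streams = tuple(sorted(parent_spawns[rec.sire]))
        rec.dam_spawn_streams = tuple(sorted(parent_spawns[rec.dam]))

    # founder records for completeness
    for pid in parent_geno:
        pedigree.append(
            PedigreeRecord(
                individual=pid,
                sire=None,
                dam=None,
                natal_stream=None,
                sire_spawn_streams=(),
                dam_spawn_streams=(),
                cohort=0,
            )
        )

    # ---- sampling --------------------------------------------------------
    ids: list[str] = []
    groups: list[str] = []
    rows: list[np.ndarray] = []
    migrant_flags: dict[str, list[bool]] = {}
    remaining: dict[str, list[tuple[str, np.ndarray, bool]]] = {}
    for stream in STREAMS:
        offspring = offspring_by_stream[stream]
        want = int(config.sample_sizes.get(stream, 0))
        if want > len(offspring):
            raise ValueError(
                f"requested {want} {stream} samples but only "
                f"{len(offspring)} offspring were generated"
            )
        order = rng.permutation(len(offspring))
        chosen = [offspring[i] for i in order[:want]]
        remaining[stream] = [offspring[i] for i in order[want:]]
        migrant_flags[stream] = [mig for _, _, mig in chosen]
        for cid, geno, _ in chosen:
            ids.append(cid)
            groups.append(stream)
            rows.append(geno)

    want_lake = int(config.sample_sizes.get("lake", 0))
    if want_lake:
        lake_pool = remaining["inflow"] + remaining["outflow"]
        if want_lake > len(lake_pool):
            raise ValueError(
                f"requested {want_lake} lake samples but only "
                f"{len(lake_pool)} unsampled offspring remain"
            )
        order = rng.permutation(len(lake_pool))
        for i in order[:want_lake]:
            cid, geno, _ = lake_pool[i]
            ids.append(cid)
            groups.append("lake")
            rows.append(geno)

    alleles = np.stack(rows)
    if config.missing_rate > 0:
        mask = rng.random(alleles.shape[:2]) < config.missing_rate
        alleles = alleles.copy()
        alleles[mask] = 0

    table = GenotypeTable(ids=ids, groups=groups, loci=[f"Loc{j+1:02d}" for j in range(config.n_loci)], alleles=alleles)
    realized = {
        f"migrant_fraction_{stream}": (
            float(np.mean(migrant_flags[stream])) if migrant_flags[stream] else 0.0
        )
        for stream in STREAMS
    }
    return pedigree, table, realized


def mixed_site_halfsib_dyads(pedigree: list[PedigreeRecord]) -> list[tuple[str, str]]:
    """True half-sib dyads whose members were born in different streams."""
    offspring = [r for r in pedigree if r.sire is not None]
    out: list[tuple[str, str]] = []
    for i in range(len(offspring)):
        for j in range(i + 1, len(offspring)):
            a, b = offspring[i], offspring[j]
            shared = int(a.sire == b.sire) + int(a.dam == b.dam)
            if shared == 1 and a.natal_stream != b.natal_stream:
                out.append((a.individual, b.individual))
    return out


# ---------------------------------------------------------------------------
# temperatures
# ---------------------------------------------------------------------------

def simulate_temperatures(
    config: SimulationConfig,
    rng: np.random.Generator,
    start: date = date(2016, 1, 1),
    n_days: int = 1200,
) -> TemperatureSeries:
    """Sinusoidal annual cycle (peak 1 August) with a winter floor.

    The floor (default 4 degC, the density maximum of fresh water) models
    the flat winter plateau of temperate lake surface series: instead of
    tracking the sinusoid to its minimum, winter temperatures hover just
    below the growth base temperature.  Gaussian daily noise is added on
    top.
    """
    days = pd.date_range(start, periods=n_days, freq="D")
    doy = days.dayofyear.to_numpy()
    seasonal = config.temp_mean + config.temp_amplitude * np.cos(
        2 * np.pi * (doy - 213) / 365.25
    )
    temps = np.maximum(seasonal, config.temp_winter_floor) + rng.normal(
        0.0, config.temp_noise_sd, size=n_days
    )
    return TemperatureSeries(pd.Series(temps, index=days))


# ---------------------------------------------------------------------------
# telemetry
# ---------------------------------------------------------------------------

def default_antennae() -> dict[str, AntennaSite]:
    return {
        "INF1": AntennaSite("INF1", INFLOW, 75),
        "INF2": AntennaSite("INF2", INFLOW, 85),
        "OUTU1": AntennaSite("OUTU1", OUTFLOW_UPPER, 40),
        "OUTU2": AntennaSite("OUTU2", OUTFLOW_UPPER, 60),
        "OUTL1": AntennaSite("OUTL1", OUTFLOW_LOWER, 9540),
    }


def _random_night_time(
    rng: np.random.Generator, nocturnality: float, night_start: time, night_end: time
) -> time:
    """A clock time, nocturnal with the configured probability."""
    night_minutes = (
        (24 * 60 - night_start.hour * 60 - night_start.minute)
        + night_end.hour * 60
        + night_end.minute
    )
    day_minutes = 24 * 60 - night_minutes
    if rng.random() < nocturnality:
        offset = int(rng.integers(0, night_minutes))
        total = (night_start.hour * 60 + night_start.minute + offset) % (24 * 60)
    else:
        offset = int(rng.integers(0, day_minutes))
        total = (night_end.hour * 60 + night_end.minute + offset) % (24 * 60)
    return time(total // 60, total % 60, 0)


def simulate_telemetry(
    config: SimulationConfig,
    tags_with_behavior: dict[str, str],
    windows: list[SpawningWindow],
    rng: np.random.Generator,
    antennae: dict[str, AntennaSite] | None = None,
) -> pd.DataFrame:
    """Detection events for mature fish with scripted behavior classes.

    ``tags_with_behavior`` maps tag id to IO / OO / B.  Each fish visits its
    stream(s) in one window chosen at random; a visit produces a Poisson
    number of antenna passes, each detected with ``detection_prob_per_pass``
    and stamped at a night-biased clock time on a uniform window date.  B
    fish visit both streams in the same window.  An empty result is legal
    (e.g. zero detection probability).
    """
    antennae = antennae or default_antennae()
    by_stream: dict[str, list[str]] = {}
    for aid, site in antennae.items():
        by_stream.setdefault(site.stream, []).append(aid)
    night_start = datetime.strptime(config.night_start, "%H:%M").time()
    night_end = datetime.strptime(config.night_end, "%H:%M").time()

    rows: list[dict] = []
    for tag in sorted(tags_with_behavior):
        behavior = tags_with_behavior[tag]
        if behavior not in ("IO", "OO", "B"):
            raise ValueError(f"unknown behavior {behavior!r} for tag {tag}")
        window = windows[int(rng.integers(0, len(windows)))]
        streams = {
            "IO": [INFLOW],
            "OO": [OUTFLOW_UPPER],
            "B": [INFLOW, OUTFLOW_UPPER],
        }[behavior]
        for stream in streams:
            n_pass = max(1, int(rng.poisson(config.passes_per_stream_visit)))
            n_days = (window.end - window.start).days + 1
            for _ in range(n_pass):
                if rng.random() >= config.detection_prob_per_pass:
                    continue
                day = window.start + timedelta(days=int(rng.integers(0, n_days)))
                clock = _random_night_time(
                    rng, config.nocturnality, night_start, night_end
                )
                rows.append(
                    {
                        "tag": tag,
                        "antenna": str(rng.choice(by_stream[stream])),
                        "timestamp": datetime.combine(day, clock),
                    }
                )
    df = pd.DataFrame(rows, columns=["tag", "antenna", "timestamp"])
    if not df.empty:
        df["timestamp"] = pd.to_datetime(df["timestamp"])
        df = df.sort_values(["timestamp", "tag"], kind="stable").reset_index(drop=True)
    return df


def scripted_behaviors(
    config: SimulationConfig, n_fish: int, rng: np.random.Generator
) -> dict[str, str]:
    """Assign IO/OO/B classes to tags from the configured proportions."""
    props = config.behavior_proportions
    classes = list(props)
    p = np.array([props[c] for c in classes], dtype=float)
    p = p / p.sum()
    draws = rng.choice(len(classes), size=n_fish, p=p)
    return {f"T{i:05d}": classes[d] for i, d in enumerate(draws)}


# ---------------------------------------------------------------------------
# growth records
# ---------------------------------------------------------------------------

def simulate_growth_records(
    config: SimulationConfig,
    temps: TemperatureSeries,
    rng: np.random.Generator,
    n_obs: int | None = None,
) -> list[GrowthObservation]:
    """Tag/recapture pairs following the degree-day growth law.

    FL1 ~ Uniform(90, 280) mm; intervals span 15-505 days inside the
    temperature series, with both capture dates in the April-October field
    season (fish are captured by electrofishing and seine netting, which
    happen in the ice-free productive months); observed growth is
    (a ln FL1 + b) * DD_T0 plus Gaussian noise of ``growth_noise_sd`` mm.
    A zero-day interval is rejected by construction (minimum 15 days).
    """
    n_obs = n_obs if n_obs is not None else config.n_growth_obs
    daily = temps.daily
    first, last = daily.index[0], daily.index[-1]
    horizon = (last - first).days
    if horizon < 520:
        raise ValueError("temperature series too short for 15-505 day intervals")
    out: list[GrowthObservation] = []
    for i in range(n_obs):
        while True:
            interval = int(rng.integers(15, 506))
            start_offset = int(rng.integers(0, horizon - interval))
            d1 = (first + timedelta(days=start_offset)).date()
            d2 = d1 + timedelta(days=interval)
            if 4 <= d1.month <= 10 and 4 <= d2.month <= 10:
                break
        fl1 = float(rng.uniform(90.0, 280.0))
        dd = degree_days(temps, config.growth_t0, d1, d2)
        growth = (config.growth_a * np.log(fl1) + config.growth_b) * dd
        noise = rng.normal(0.0, config.growth_noise_sd) if config.growth_noise_sd else 0.0
        out.append(
            GrowthObservation(
                tag=f"G{i:04d}", fl1=fl1, fl2_obs=fl1 + growth + noise,
                date1=d1, date2=d2,
            )
        )
    return out


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimulationConfig | None = None) -> SimulatedDataset:
    """Generate the complete linked dataset from one seeded generator."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    freqs = simulate_allele_frequencies(config, rng)
    pedigree, table, realized = simulate_pedigree_and_genotypes(config, freqs, rng)
    temps = simulate_temperatures(config, rng)
    windows = [SpawningWindow.for_season(2017), SpawningWindow.for_season(2018)]
    behaviors = scripted_behaviors(config, n_fish=208, rng=rng)
    detections = simulate_telemetry(config, behaviors, windows, rng)
    captures = simulate_growth_records(config, temps, rng)
    truth = {
        "config": asdict(config),
        **realized,
        "behavior_counts": {
            c: sum(1 for b in behaviors.values() if b == c) for c in ("IO", "OO", "B")
        },
        "n_mixed_site_halfsib_dyads": len(mixed_site_halfsib_dyads(pedigree)),
    }
    return SimulatedDataset(
        config=config,
        genotypes=table,
        pedigree=pedigree,
        detections=detections,
        behaviors=behaviors,
        captures=captures,
        temperatures=temps,
        truth=truth,
    )
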