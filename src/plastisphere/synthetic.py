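"""Synthetic data generators with planted ground truth.

Every input the analysis pipeline consumes can be generated here: an ASV
count time series with planted early/middle/late colonisers, a reference
genome collection (16S genes, proteomes, a trait table and query ASVs at
controlled identities), FTIR-like spectra with Gaussian peaks on a linear
baseline, and log-normal protein intensity tables with planted fold
changes.  Each generator returns the data *and* a truth table sufficient to
score the downstream stage that consumes it.

The community generator emulates a six-week incubation experiment:
treatments (a no-carbon control, amorphous PET biofilm and planktonic
fractions, PET powder, weathered PET powder and the PET monomer BHET)
sampled on days 1, 3, 7, 14, 21, 30 and 42 in triplicate, with read depths
bounded below by 4,000 and averaging 19,000 per sample.  Counts are drawn
from a Dirichlet-multinomial so replicate variability exceeds the
multinomial floor, as is typical for amplicon data.

All generators are deterministic under a fixed seed; independent streams
are derived from the master seed so adding one generator call never
perturbs another.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CountMatrix

logger = logging.getLogger(__name__)

BASES = np.array(list("ACGT"))
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: default treatments of the incubation design (control + five substrates)
DEFAULT_TREATMENTS = (
    "no carbon control",
    "amorphous PET biofilm",
    "amorphous PET planktonic",
    "PET powder",
    "weathered PET powder",
    "BHET",
)
DEFAULT_DAYS = (1, 3, 7, 14, 21, 30, 42)

#: serine-hydrolase-like protein motif planted into carrier proteomes;
#: contains the G-x-S-x-G nucleophile elbow typical of PET hydrolases.
DEFAULT_MOTIF = "LAVMGHSMGGGGTLRLASQRPDLKAAIPLTPWHLNKNWSSVTVPTLIIGAD"


class ScenarioError(ValueError):
    """Raised when a scenario violates its invariants."""


def _rng(seed: int, stream: int) -> np.random.Generator:
    """Deterministic child stream derived from the master seed."""
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(stream))))


# ---------------------------------------------------------------------------
# community time series
# ---------------------------------------------------------------------------


@dataclass
class ASVProfile:
    """Temporal response of one planted ASV.

    ``width`` is in units of day *index* (the sampling days are roughly
    log-spaced, so a Gaussian over the index encodes "peaks on day d"
    symmetrically).  ``treatments`` restricts the ASV to a subset of
    treatments; ``None`` means present everywhere.
    """

    peak_day: int
    peak_abundance: float
    width: float = 0.75
    treatments: tuple[str, ...] | None = None


@dataclass
class SuccessionScenario:
    treatments: tuple[str, ...] = DEFAULT_TREATMENTS
    days: tuple[int, ...] = DEFAULT_DAYS
    replicates: int = 3
    depth_range: tuple[float, float] = (4000, 19000)  # (min, mean) reads
    asv_profiles: list[ASVProfile] = field(default_factory=list)
    n_background: int = 150
    dispersion: float | None = 500.0  # Dirichlet concentration; None = noise-free
    depth_sigma: float = 0.5  # log-sd of the lognormal depth model
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.treatments or not self.days:
            raise ScenarioError("treatments and days must be non-empty")
        if list(self.days) != sorted(set(self.days)):
            raise ScenarioError("days must be strictly increasing")
        if self.replicates < 1:
            raise ScenarioError("replicates must be >= 1")
        dmin, dmean = self.depth_range
        if not (0 < dmin <= dmean):
            raise ScenarioError("depth_range must satisfy 0 < min <= mean")
        for p in self.asv_profiles:
            if p.peak_day not in self.days:
                raise ScenarioError(f"peak day {p.peak_day} not a sampling day")
            if not (0 < p.peak_abundance <= 1):
                raise ScenarioError("peak abundance must be in (0, 1]")
            if p.width <= 0:
                raise ScenarioError("profile width must be > 0")
            if p.treatments is not None:
                unknown = set(p.treatments) - set(self.treatments)
                if unknown:
                    raise ScenarioError(f"unknown treatments {unknown}")


def classify_peak_day(day: int) -> str:
    """Coloniser class for a peak day: 1-7 early, 14-30 middle, 42 late."""
    if 1 <= day <= 7:
        return "early"
    if 14 <= day <= 30:
        return "middle"
    if day >= 42:
        return "late"
    raise ValueError(f"day {day} falls outside the coloniser bins")


def default_succession_scenario(seed: int = 0) -> SuccessionScenario:
    """The standard synthetic incubation: planted colonisers of all classes.

    Nine early (peaks on days 1/3/7), nine middle (14/21/30) and three late
    (42) ASVs shared across treatments; three biofilm-restricted and three
    BHET-restricted early drivers; and three broad, persistent
    treatment-restricted ASVs per treatment, so that communities diverge by
    substrate (as observed in such incubations) and not only over time.
    Peak relative abundances of 2-12% keep every planted taxon above the
    0.5% inclusion threshold.
    """
    profiles: list[ASVProfile] = []
    rng = _rng(seed, 900)
    for peak in (1, 3, 7, 14, 21, 30):
        for _ in range(3):
            profiles.append(ASVProfile(peak, float(rng.uniform(0.02, 0.06))))
    for _ in range(3):
        profiles.append(ASVProfile(42, float(rng.uniform(0.02, 0.06))))
    for _ in range(3):
        profiles.append(
            ASVProfile(3, float(rng.uniform(0.03, 0.07)),
                       treatments=("amorphous PET biofilm",))
        )
    for _ in range(3):
        profiles.append(
            ASVProfile(3, float(rng.uniform(0.03, 0.07)), treatments=("BHET",))
        )
    for treatment in DEFAULT_TREATMENTS:
        for peak in (3, 14, 30):
            profiles.append(
                ASVProfile(peak, float(rng.uniform(0.06, 0.12)), width=1.5,
                           treatments=(treatment,))
            )
    return SuccessionScenario(asv_profiles=profiles, seed=seed)


def _sample_depths(rng, n, depth_min, depth_mean, sigma):
    """Lognormal depths truncated below at ``depth_min`` via resampling."""
    mu = np.log(depth_mean) - sigma**2 / 2.0
    depths = rng.lognormal(mu, sigma, size=n)
    while (bad := depths < depth_min).any():
        depths[bad] = rng.lognormal(mu, sigma, size=int(bad.sum()))
    return np.round(depths).astype(int)


def _largest_remainder(p: np.ndarray, total: int) -> np.ndarray:
    """Integer counts summing exactly to ``total`` with proportions ~ p."""
    raw = p * total
    counts = np.floor(raw).astype(int)
    short = total - counts.sum()
    if short > 0:
        order = np.argsort(-(raw - counts))
        counts[order[:short]] += 1
    return counts


def generate_community_series(
    scenario: SuccessionScenario,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Simulate the ASV count time series.

    Returns
    -------
    (CountMatrix, truth)
        ``truth`` has one row per planted ASV: ``coloniser_class``,
        ``peak_day``, ``peak_abundance``, ``driver_treatments`` (semicolon
        joined, empty if unrestricted) and ``background`` (bool, False for
        planted taxa; background rows are appended with True).
    """
    scn = scenario
    days = np.asarray(scn.days)
    day_index = {d: i for i, d in enumerate(scn.days)}

    n_planted = len(scn.asv_profiles)
    asv_ids = [f"ASV_{i + 1:04d}" for i in range(n_planted + scn.n_background)]
    planted_ids = asv_ids[:n_planted]
    background_ids = asv_ids[n_planted:]

    rng_bg = _rng(scn.seed, 1)
    # background taxa: flat lognormal baseline intensities, scaled so the
    # background occupies roughly the mass the planted taxa leave free
    bg_levels = rng_bg.lognormal(0.0, 1.0, size=scn.n_background)
    planted_mass = np.zeros(len(days))
    for p in scn.asv_profiles:
        idx = day_index[p.peak_day]
        planted_mass += p.peak_abundance * np.exp(
            -0.5 * ((np.arange(len(days)) - idx) / p.width) ** 2
        )
    target_bg = max(0.2, 1.0 - float(planted_mass.mean()))
    bg_levels = bg_levels / bg_levels.sum() * target_bg

    rng_depth = _rng(scn.seed, 2)
    rng_counts = _rng(scn.seed, 3)

    columns, meta_rows = [], []
    count_cols = {}
    for treatment in scn.treatments:
        for day in scn.days:
            for rep in range(1, scn.replicates + 1):
                sid = f"{treatment.replace(' ', '_')}.d{day}.r{rep}"
                idx = day_index[day]
                intensity = np.empty(len(asv_ids))
                for k, p in enumerate(scn.asv_profiles):
                    if p.treatments is not None and treatment not in p.treatments:
                        intensity[k] = 0.0
                    else:
                        intensity[k] = p.peak_abundance * np.exp(
                            -0.5 * ((idx - day_index[p.peak_day]) / p.width) ** 2
                        )
                intensity[n_planted:] = bg_levels
                props = intensity / intensity.sum()

                depth = int(
                    _sample_depths(
                        rng_depth, 1, scn.depth_range[0], scn.depth_range[1],
                        scn.depth_sigma,
                    )[0]
                )
                if scn.dispersion is None:
                    counts = _largest_remainder(props, depth)
                elif np.isinf(scn.dispersion):
                    counts = rng_counts.multinomial(depth, props)
                else:
                    alpha = scn.dispersion * props
                    # Dirichlet with zero alphas: keep structural zeros at 0
                    nz = alpha > 0
                    p_draw = np.zeros_like(props)
                    p_draw[nz] = rng_counts.dirichlet(alpha[nz])
                    counts = rng_counts.multinomial(depth, p_draw)
                count_cols[sid] = counts
                columns.append(sid)
                meta_rows.append(
                    {"sample_id": sid, "treatment": treatment, "day": day,
                     "replicate": rep}
                )

    counts_df = pd.DataFrame(count_cols, index=asv_ids)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    truth_rows = []
    for aid, p in zip(planted_ids, scn.asv_profiles):
        truth_rows.append(
            {
                "asv": aid,
                "coloniser_class": classify_peak_day(p.peak_day),
                "peak_day": p.peak_day,
                "peak_abundance": p.peak_abundance,
                "driver_treatments": ";".join(p.treatments or ()),
                "background": False,
            }
        )
    for aid in background_ids:
        truth_rows.append(
            {"asv": aid, "coloniser_class": "", "peak_day": -1,
             "peak_abundance": np.nan, "driver_treatments": "", "background": True}
        )
    truth = pd.DataFrame(truth_rows).set_index("asv")
    return CountMatrix(counts_df, meta), truth


# ---------------------------------------------------------------------------
# reference genome collection
# ---------------------------------------------------------------------------


@dataclass
class ReferenceScenario:
    n_genomes: int = 20
    identity_ladder: tuple[float, ...] = (1.0, 0.99, 0.97, 0.95, 0.90)
    motif: str = DEFAULT_MOTIF
    motif_carriers: frozenset[str] | None = None  # None -> first quarter
    copies_per_carrier: int = 2
    background_families: int = 10
    ssu_length: int = 1200
    proteins_per_genome: int = 12
    protein_length: int = 240
    n_seed_sequences: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes < 1:
            raise ScenarioError("need at least one genome")
        for ident in self.identity_ladder:
            if not (0.7 <= ident <= 1.0):
                raise ScenarioError(f"identity {ident} outside [0.7, 1.0]")
        if self.copies_per_carrier < 1:
            raise ScenarioError("copies_per_carrier must be >= 1")
        if len(self.motif) > self.protein_length:
            raise ScenarioError("motif longer than generated proteins")

    def genome_ids(self) -> list[str]:
        return [f"g{i:04d}" for i in range(self.n_genomes)]

    def carriers(self) -> frozenset[str]:
        if self.motif_carriers is not None:
            unknown = set(self.motif_carriers) - set(self.genome_ids())
            if unknown:
                raise ScenarioError(f"carriers not in genome set: {unknown}")
            return frozenset(self.motif_carriers)
        return frozenset(self.genome_ids()[: max(1, self.n_genomes // 4)])


def _mutate_to_identity(seq: str, identity: float, rng) -> tuple[str, float]:
    """Substitute exactly round((1-identity)*L) positions; no indels.

    The realised identity is exact by construction, which makes
    identity-threshold tests deterministic.
    """
    length = len(seq)
    n_sub = int(round((1.0 - identity) * length))
    positions = rng.choice(length, size=n_sub, replace=False)
    chars = np.array(list(seq))
    for pos in positions:
        choices = [b for b in "ACGT" if b != chars[pos]]
        chars[pos] = choices[rng.integers(len(choices))]
    return "".join(chars), 1.0 - n_sub / length


def generate_reference_collection(scenario: ReferenceScenario):
    """Simulate genomes, proteomes, a trait table and query ASVs.

    Returns a dict with keys ``reference_16s`` (genome id -> sequence),
    ``proteomes`` (genome id -> {protein id: sequence}), ``traits``
    (DataFrame genome x family incl. the planted custom-family truth
    column), ``asv_seqs`` (ASV id -> sequence), ``seed_alignment``
    (id -> aligned sequence, gapless) and ``truth`` (DataFrame per ASV:
    source genome, target/realised identity, carrier status).
    """
    scn = scenario
    genomes = scn.genome_ids()
    carriers = scn.carriers()

    rng_seq = _rng(scn.seed, 10)
    reference_16s = {
        g: "".join(rng_seq.choice(BASES, size=scn.ssu_length)) for g in genomes
    }

    rng_prot = _rng(scn.seed, 11)
    aa = np.array(list(AMINO_ACIDS))
    proteomes: dict[str, dict[str, str]] = {}
    trait_truth = {}
    for g in genomes:
        prots = {
            f"{g}_p{j:03d}": "".join(rng_prot.choice(aa, size=scn.protein_length))
            for j in range(scn.proteins_per_genome)
        }
        if g in carriers:
            chosen = rng_prot.choice(
                sorted(prots), size=scn.copies_per_carrier, replace=False
            )
            for pid in chosen:
                seq = list(prots[pid])
                start = int(
                    rng_prot.integers(0, scn.protein_length - len(scn.motif) + 1)
                )
                motif = list(scn.motif)
                # small corruption: two random substitutions
                for pos in rng_prot.choice(len(motif), size=2, replace=False):
                    motif[pos] = str(rng_prot.choice(aa))
                seq[start : start + len(motif)] = motif
                prots[pid] = "".join(seq)
            trait_truth[g] = scn.copies_per_carrier
        else:
            trait_truth[g] = 0
        proteomes[g] = prots

    rng_traits = _rng(scn.seed, 12)
    traits = pd.DataFrame(
        rng_traits.integers(0, 4, size=(len(genomes), scn.background_families)),
        index=genomes,
        columns=[f"fam{j:03d}" for j in range(scn.background_families)],
    )
    traits["planted_family_truth"] = pd.Series(trait_truth)

    rng_asv = _rng(scn.seed, 13)
    asv_seqs, truth_rows = {}, []
    for i, g in enumerate(genomes):
        target = scn.identity_ladder[i % len(scn.identity_ladder)]
        seq, realised = _mutate_to_identity(reference_16s[g], target, rng_asv)
        aid = f"asv{i:04d}"
        asv_seqs[aid] = seq
        truth_rows.append(
            {"asv": aid, "source_genome": g, "target_identity": target,
             "realised_identity": realised, "carrier": g in carriers}
        )
    truth = pd.DataFrame(truth_rows).set_index("asv")

    rng_seed_aln = _rng(scn.seed, 14)
    seed_alignment = {}
    for s in range(scn.n_seed_sequences):
        variant = list(scn.motif)
        pos = int(rng_seed_aln.integers(len(variant)))
        variant[pos] = str(rng_seed_aln.choice(aa))
        seed_alignment[f"seed{s:02d}"] = "".join(variant)

    return {
        "reference_16s": reference_16s,
        "proteomes": proteomes,
        "traits": traits,
        "asv_seqs": asv_seqs,
        "seed_alignment": seed_alignment,
        "truth": truth,
    }


# ---------------------------------------------------------------------------
# FTIR-like spectra
# ---------------------------------------------------------------------------

#: the five diagnostic wavenumbers (cm^-1): aromatic C-H, ester C-O,
#: carboxylic C-O, the invariant reference band, carboxylic C=O
OXIDATION_WAVENUMBERS = (725.0, 1090.0, 1240.0, 1410.0, 1711.0)


@dataclass
class SpectrumScenario:
    peak_centres: tuple[float, ...] = OXIDATION_WAVENUMBERS
    peak_heights: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "control": (0.30, 0.90, 0.45, 0.60, 0.75),
            "incubated": (0.39, 1.17, 0.585, 0.60, 0.975),
        }
    )
    peak_width: float = 22.0  # Gaussian sigma, cm^-1
    baseline_slope: float = 2e-5  # absorbance per cm^-1
    noise_sd: float = 0.005
    n_spectra: int = 3
    grid: tuple[float, float, float] = (4000.0, 600.0, 2.0)  # start, stop, step
    seed: int = 0

    def __post_init__(self) -> None:
        start, stop, step = self.grid
        if not (start > stop and 0 < step <= 2.0):
            raise ScenarioError("grid must descend with step <= 2 cm^-1")
        for c in self.peak_centres:
            if not (stop <= c <= start):
                raise ScenarioError(f"peak centre {c} outside grid")
        if self.peak_width <= 0:
            raise ScenarioError("peak width must be > 0")
        if self.noise_sd < 0:
            raise ScenarioError("noise_sd must be >= 0")
        for group, heights in self.peak_heights.items():
            if len(heights) != len(self.peak_centres):
                raise ScenarioError(f"group {group}: wrong number of heights")
            if any(h < 0 for h in heights):
                raise ScenarioError(f"group {group}: negative peak height")
        centres = sorted(self.peak_centres)
        for a, b in zip(centres, centres[1:]):
            if b - a < self.peak_width:
                warnings.warn(
                    f"peaks at {a} and {b} cm^-1 closer than one width; "
                    "heights will blend",
                    stacklevel=2,
                )


def generate_spectra(scenario: SpectrumScenario):
    """Simulate per-group spectra on a descending wavenumber grid.

    Returns ``(spectra, truth)`` where ``spectra`` maps
    ``(group, replicate)`` to an absorbance array and ``truth`` is a
    DataFrame of planted peak heights (group x centre).  The shared
    wavenumber grid is under key ``"wavenumbers"`` of the returned dict.
    """
    scn = scenario
    start, stop, step = scn.grid
    wn = np.arange(start, stop - step / 2, -step)
    rng = _rng(scn.seed, 20)
    spectra: dict = {"wavenumbers": wn}
    for group in sorted(scn.peak_heights):
        heights = scn.peak_heights[group]
        signal = scn.baseline_slope * (wn - stop)
        for centre, h in zip(scn.peak_centres, heights):
            signal = signal + h * np.exp(-0.5 * ((wn - centre) / scn.peak_width) ** 2)
        for rep in range(1, scn.n_spectra + 1):
            noise = rng.normal(0.0, scn.noise_sd, size=wn.size) if scn.noise_sd else 0.0
            spectra[(group, rep)] = signal + noise
    truth = pd.DataFrame(
        {g: list(h) for g, h in scn.peak_heights.items()},
        index=[f"{c:g}" for c in scn.peak_centres],
    ).T
    return spectra, truth


# ---------------------------------------------------------------------------
# geolocated community samples (biogeography screen input)
# ---------------------------------------------------------------------------


def generate_geo_samples(asv_ids, n_samples: int = 12, seed: int = 0):
    """Relative-abundance table plus lat/lon metadata for geolocated samples.

    Dirichlet community compositions over ``asv_ids`` at uniformly random
    ocean-ish coordinates; used to exercise identity-threshold matching and
    5-degree gridding.  Returns ``(rel, metadata)``.
    """
    asv_ids = list(asv_ids)
    rng = _rng(seed, 40)
    rel = pd.DataFrame(
        rng.dirichlet(np.ones(len(asv_ids)), size=n_samples).T,
        index=asv_ids,
        columns=[f"geo{s:03d}" for s in range(n_samples)],
    )
    meta = pd.DataFrame(
        {
            "latitude": rng.uniform(-65, 65, size=n_samples),
            "longitude": rng.uniform(-180, 180, size=n_samples),
            "sample_type": rng.choice(["PET", "PE", "PVC", "water"], size=n_samples),
        },
        index=rel.columns,
    )
    return rel, meta


# ---------------------------------------------------------------------------
# proteomic intensity tables
# ---------------------------------------------------------------------------


def generate_intensity_table(
    planted_fold_changes,
    n_per_group: int = 3,
    cv: float = 0.2,
    base_intensity: float = 1e6,
    seed: int = 0,
):
    """Log-normal protein intensities for two conditions (A control, B).

    ``planted_fold_changes`` is a sequence (or mapping protein id -> FC) of
    multiplicative effects of condition B relative to A; all must be > 0.
    Returns ``(intensities, labels, truth)``: a protein x sample DataFrame,
    a Series of condition labels, and the planted fold-change table.
    """
    if n_per_group < 2:
        raise ScenarioError("n_per_group must be >= 2 for a t-test")
    if isinstance(planted_fold_changes, dict):
        proteins = list(planted_fold_changes)
        fcs = np.array([planted_fold_changes[p] for p in proteins], dtype=float)
    else:
        fcs = np.asarray(planted_fold_changes, dtype=float)
        proteins = [f"prot{i:04d}" for i in range(len(fcs))]
    if (fcs <= 0).any():
        raise ScenarioError("fold changes must be > 0")

    rng = _rng(seed, 30)
    sigma = np.sqrt(np.log1p(cv**2))
    base = base_intensity * rng.lognormal(0.0, 1.0, size=len(fcs))
    cols, labels = {}, {}
    for cond, mult in (("A", np.ones_like(fcs)), ("B", fcs)):
        for rep in range(1, n_per_group + 1):
            sid = f"{cond}{rep}"
            noise = rng.lognormal(0.0, sigma, size=len(fcs)) if cv > 0 else 1.0
            cols[sid] = base * mult * noise
            labels[sid] = cond
    intensities = pd.DataFrame(cols, index=proteins)
    truth = pd.DataFrame({"fold_change": fcs}, index=proteins)
    return intensities, pd.Series(labels, name="condition"), truth
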