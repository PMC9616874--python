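"""Synthetic dilution-to-extinction cultivation arrays with planted interactions.

The generator emulates the study conditions of a 96-well cultivation
experiment: a source community (log-normal rank-abundance) is serially
diluted 10^-1..10^-7 and dispensed into plates, so the expected number of
founding cells of species *s* per well is

    lambda_s = cells_per_ul * inoculum_volume_ul * abundance_s * 10^-dilution_level

and the realized seeding is Poisson(lambda_s), independent per species and
well (an optional co-colonization mode correlates the seeding of positive
partners). Seeded species grow to a per-well endpoint where each species'
final share is its seeded share multiplied by exp(sign * effect_size) for
every co-seeded interaction partner, renormalized — a multiplicative
share perturbation rather than an integrated dynamical model, since the
downstream inference consumes endpoint abundances only. Sequencing is
Multinomial(read_depth, final shares); wells with zero seeded cells yield
all-zero rows, which are retained (growth detection happens downstream).

Also provided: labeled mono-/co-culture growth curves for the six pairwise
interaction archetypes, synthetic Zotu V4 and isolate 16S sequences, and
synthetic qPCR standard-curve readouts, so every downstream stage of the
pipeline can be exercised without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .tables import PlateDesign, PlateTable, well_ids

__all__ = [
    "SourceCommunity",
    "InteractionTruth",
    "GrowthCurveSet",
    "INTERACTION_LABELS",
    "simulate_source",
    "simulate_plate",
    "simulate_growth_curves",
    "simulate_zotu_sequences",
    "simulate_isolate_sequences",
    "simulate_qpcr_standard",
    "write_truth_pairs",
    "write_growth_curves",
    "read_growth_curves",
]

INTERACTION_LABELS = (
    "neutralism",
    "competition",
    "mutualism",
    "commensalism",
    "amensalism",
    "exploitation",
)


@dataclass(frozen=True)
class SourceCommunity:
    """The community being diluted: species labels, relative abundances, density."""

    species_ids: tuple[str, ...]
    abundances: np.ndarray = field(repr=False)
    cells_per_ul: float

    def __post_init__(self) -> None:
        ab = np.asarray(self.abundances, dtype=float)
        if len(self.species_ids) != ab.size:
            raise ValueError("species_ids and abundances length mismatch")
        if len(set(self.species_ids)) != len(self.species_ids):
            raise ValueError("species_ids must be unique")
        if ab.size and ab.min() < 0:
            raise ValueError("abundances must be non-negative")
        if abs(ab.sum() - 1.0) > 1e-9:
            raise ValueError(f"abundances must sum to 1 (got {ab.sum()})")
        if self.cells_per_ul <= 0:
            raise ValueError("cells_per_ul must be positive")
        object.__setattr__(self, "species_ids", tuple(self.species_ids))
        object.__setattr__(self, "abundances", ab)


@dataclass(frozen=True)
class InteractionTruth:
    """Ground-truth planted pairs: (species_a, species_b, sign in {+1,-1}, effect_size >= 0)."""

    pairs: tuple[tuple[str, str, int, float], ...]

    def __post_init__(self) -> None:
        seen = set()
        for a, b, sign, effect in self.pairs:
            if a == b:
                raise ValueError(f"self-pair {a!r}")
            if sign not in (+1, -1):
                raise ValueError(f"sign must be +1 or -1, got {sign}")
            if effect < 0:
                raise ValueError("effect_size must be >= 0")
            key = frozenset((a, b))
            if key in seen:
                raise ValueError(f"duplicate pair {a}-{b}")
            seen.add(key)
        object.__setattr__(self, "pairs", tuple(self.pairs))

    @property
    def pair_keys(self) -> set[frozenset]:
        return {frozenset((a, b)) for a, b, _, _ in self.pairs}

    def matrix(self, species_ids: Sequence[str]) -> np.ndarray:
        """Signed-effect matrix M[i,j] = sign*effect for planted (i,j), 0 otherwise."""
        index = {s: i for i, s in enumerate(species_ids)}
        m = np.zeros((len(species_ids), len(species_ids)))
        for a, b, sign, effect in self.pairs:
            i, j = index[a], index[b]
            m[i, j] = m[j, i] = sign * effect
        return m


def simulate_source(
    n_species: int,
    lognormal_mu: float = 0.0,
    lognormal_sigma: float = 1.0,
    cells_per_ul: float = 1e6,
    seed: int | None = None,
    prefix: str = "Zotu",
) -> SourceCommunity:
    """Draw a log-normal rank-abundance community; deterministic given seed."""
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    if lognormal_sigma < 0:
        raise ValueError("lognormal_sigma must be >= 0")
    if cells_per_ul <= 0:
        raise ValueError("cells_per_ul must be positive")
    rng = np.random.default_rng(seed)
    masses = rng.lognormal(mean=lognormal_mu, sigma=lognormal_sigma, size=n_species)
    abundances = masses / masses.sum()
    species_ids = tuple(f"{prefix}{i + 1}" for i in range(n_species))
    return SourceCommunity(species_ids=species_ids, abundances=abundances, cells_per_ul=cells_per_ul)


def seeding_rates(source: SourceCommunity, design: PlateDesign) -> np.ndarray:
    """Expected founding cells per well per species: the Poisson intensities."""
    scale = source.cells_per_ul * design.inoculum_volume_ul * 10.0 ** (-design.dilution_level)
    return source.abundances * scale


def simulate_plate(
    source: SourceCommunity,
    truth: InteractionTruth,
    design: PlateDesign,
    read_depth: int = 10_000,
    seed: int | None = None,
    co_colonization: bool = False,
) -> tuple[PlateTable, np.ndarray]:
    """Simulate one plate; returns (PlateTable, boolean seeded-occupancy truth).

    ``co_colonization=True`` additionally correlates the *seeding* of each
    positive planted pair (a shared per-well Bernoulli gate doubling or
    zeroing both partners' intensities, mean preserved), emulating joint
    dispersal rather than purely post-seeding interaction.
    """
    if read_depth < 0:
        raise ValueError("read_depth must be >= 0")
    rng = np.random.default_rng(seed)
    n_wells, n_species = design.n_wells, len(source.species_ids)
    lam = np.broadcast_to(seeding_rates(source, design), (n_wells, n_species)).copy()

    index = {s: i for i, s in enumerate(source.species_ids)}
    if co_colonization:
        for a, b, sign, _ in truth.pairs:
            if sign > 0:
                gate = rng.random(n_wells) < 0.5
                lam[:, index[a]] *= 2.0 * gate
                lam[:, index[b]] *= 2.0 * gate

    seeded = rng.poisson(lam)
    occupied = seeded.sum(axis=1) > 0
    present = seeded > 0

    with np.errstate(invalid="ignore", divide="ignore"):
        shares = seeded / seeded.sum(axis=1, keepdims=True)
    shares = np.nan_to_num(shares)

    # multiplicative endpoint perturbation: boost/suppress both partners in
    # wells where both were seeded
    for a, b, sign, effect in truth.pairs:
        i, j = index[a], index[b]
        both = present[:, i] & present[:, j]
        factor = np.exp(sign * effect)
        shares[both, i] *= factor
        shares[both, j] *= factor
    totals = shares.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        shares = np.nan_to_num(shares / totals)

    counts = np.zeros((n_wells, n_species), dtype=np.int64)
    if read_depth > 0 and occupied.any():
        counts[occupied] = rng.multinomial(read_depth, shares[occupied])

    plate = PlateTable(
        plate_id=design.plate_id,
        design=design,
        wells=well_ids(n_wells),
        zotu_ids=source.species_ids,
        counts=counts,
    )
    return plate, occupied


# ---------------------------------------------------------------------------
# growth curves

@dataclass(frozen=True)
class GrowthCurveSet:
    """Mono- and co-culture density series of an isolate pair on a shared time grid."""

    times: np.ndarray
    mono_a: np.ndarray
    mono_b: np.ndarray
    co_a: np.ndarray
    co_b: np.ndarray
    label: str | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.size < 2 or not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing with >= 2 points")
        for name in ("mono_a", "mono_b", "co_a", "co_b"):
            series = np.asarray(getattr(self, name), dtype=float)
            if series.shape != t.shape:
                raise ValueError(f"{name} length differs from times")
            if series.size and series.min() < 0:
                raise ValueError(f"{name} contains negative densities")
            object.__setattr__(self, name, series)
        object.__setattr__(self, "times", t)


# co-culture carrying-capacity multipliers (partner A, partner B) per label;
# >1 facilitated, <1 suppressed, 1 unaffected
_LABEL_MULTIPLIERS = {
    "neutralism": (1.0, 1.0),
    "competition": (0.35, 0.35),
    "mutualism": (3.0, 3.0),
    "commensalism": (3.0, 1.0),
    "amensalism": (0.35, 1.0),
    "exploitation": (3.0, 0.35),
}


def _logistic(times: np.ndarray, n0: float, rate: float, capacity: float) -> np.ndarray:
    e = np.exp(rate * times)
    return capacity * n0 * e / (capacity + n0 * (e - 1.0))


def simulate_growth_curves(
    label: str,
    times: np.ndarray | None = None,
    n0: float = 1e5,
    rate_a: float = 0.6,
    rate_b: float = 0.5,
    capacity: float = 1e9,
    noise_sd: float = 0.1,
    seed: int | None = None,
) -> GrowthCurveSet:
    """Labeled logistic mono-/co-culture curves for one interaction archetype.

    Each partner grows logistically (rate per hour, shared carrying capacity
    in cells/ml); in co-culture the capacity is scaled by the label's
    multiplier pair, so e.g. competition depresses both partners and
    exploitation raises one while depressing the other. Noise is
    multiplicative log-normal with sd ``noise_sd`` (natural-log scale).
    """
    if label not in _LABEL_MULTIPLIERS:
        raise ValueError(f"unknown interaction label {label!r}; expected one of {INTERACTION_LABELS}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if times is None:
        times = np.arange(0.0, 36.5, 1.5)
    times = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    mult_a, mult_b = _LABEL_MULTIPLIERS[label]

    mono_a = _logistic(times, n0, rate_a, capacity)
    mono_b = _logistic(times, n0, rate_b, capacity)
    co_a = _logistic(times, n0, rate_a, capacity * mult_a)
    co_b = _logistic(times, n0, rate_b, capacity * mult_b)
    if noise_sd > 0:
        noise = rng.lognormal(mean=0.0, sigma=noise_sd, size=(4, times.size))
        mono_a, mono_b, co_a, co_b = mono_a * noise[0], mono_b * noise[1], co_a * noise[2], co_b * noise[3]
    return GrowthCurveSet(times=times, mono_a=mono_a, mono_b=mono_b, co_a=co_a, co_b=co_b, label=label)


# ---------------------------------------------------------------------------
# sequences

_V4_FWD = "GTGYCAGCMGCCGCGGTAA"
_V4_REV = "GGACTACNVGGGTWTCTAAT"
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def simulate_zotu_sequences(
    species_ids: Sequence[str],
    length: int = 250,
    seed: int | None = None,
) -> dict[str, str]:
    """Random V4-like representative sequences, one per Zotu (synthetic)."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    return {s: "".join(rng.choice(bases, size=length)) for s in species_ids}


def simulate_isolate_sequences(
    zotu_v4: dict[str, str],
    n_isolates_per_zotu: int = 2,
    n_unrelated: int = 0,
    flank_length: int = 120,
    mutation_rate: float = 0.0,
    seed: int | None = None,
    fwd_primer: str = _V4_FWD,
    rev_primer: str = _V4_REV,
) -> tuple[dict[str, str], dict[str, str]]:
    """Near-full-length synthetic isolate 16S sequences embedding a V4 amplicon.

    Each isolate sequence is flank + forward primer + V4 + revcomp(reverse
    primer) + flank, where the V4 copies a Zotu's sequence with per-base
    ``mutation_rate``. ``n_unrelated`` isolates carry a random V4 matching no
    Zotu. Returns (isolate_seqs, isolate->source-zotu truth; unrelated map
    to "")."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))

    def random_seq(n: int) -> str:
        return "".join(rng.choice(bases, size=n))

    def mutate(seq: str) -> str:
        if mutation_rate <= 0:
            return seq
        out = list(seq)
        for i in range(len(out)):
            if rng.random() < mutation_rate:
                out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
        return "".join(out)

    isolates: dict[str, str] = {}
    truth: dict[str, str] = {}
    k = 0
    for zotu, v4 in zotu_v4.items():
        for _ in range(n_isolates_per_zotu):
            k += 1
            name = f"ISO-{k}"
            isolates[name] = (
                random_seq(flank_length) + fwd_primer + mutate(v4) + _revcomp(rev_primer) + random_seq(flank_length)
            )
            truth[name] = zotu
    v4_len = len(next(iter(zotu_v4.values()))) if zotu_v4 else 250
    for _ in range(n_unrelated):
        k += 1
        name = f"ISO-{k}"
        isolates[name] = (
            random_seq(flank_length) + fwd_primer + random_seq(v4_len) + _revcomp(rev_primer) + random_seq(flank_length)
        )
        truth[name] = ""
    return isolates, truth


def simulate_qpcr_standard(
    slope: float = -3.3219,
    intercept: float = 35.0,
    log10_copies: Sequence[float] = tuple(range(1, 9)),
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Synthetic qPCR dilution series: Cq = slope*log10(copies) + intercept + noise."""
    rng = np.random.default_rng(seed)
    log10_copies = np.asarray(log10_copies, dtype=float)
    cq = slope * log10_copies + intercept + rng.normal(0.0, noise_sd, size=log10_copies.size)
    return pd.DataFrame({"log10_copies": log10_copies, "cq": cq})


# ---------------------------------------------------------------------------
# writers

def write_truth_pairs(truth: InteractionTruth, path: str | Path) -> None:
    rows = [
        {"species_a": a, "species_b": b, "sign": sign, "effect_size": effect}
        for a, b, sign, effect in truth.pairs
    ]
    pd.DataFrame(rows, columns=["species_a", "species_b", "sign", "effect_size"]).to_csv(
        path, sep="\t", index=False
    )


def write_growth_curves(curves: GrowthCurveSet, path: str | Path) -> None:
    frames = []
    for name in ("mono_a", "mono_b", "co_a", "co_b"):
        frames.append(
            pd.DataFrame({"time_h": curves.times, "series": name, "density": getattr(curves, name)})
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_growth_curves(path: str | Path, label: str | None = None) -> GrowthCurveSet:
    df = pd.read_csv(path)
    series = {}
    times = None
    for name, sub in df.groupby("series"):
        sub = sub.sort_values("time_h")
        series[name] = sub["density"].to_numpy()
        times = sub["time_h"].to_numpy()
    return GrowthCurveSet(
        times=times,
        mono_a=series["mono_a"],
        mono_b=series["mono_b"],
        co_a=series["co_a"],
        co_b=series["co_b"],
        label=label,
    )
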