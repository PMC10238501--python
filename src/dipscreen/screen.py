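"""Stochastic simulation of iterative dark/light FACS selection.

Each library variant has a single-cell GFP expression distribution in the dark
and under blue light, modelled as autofluorescence floor + log-normal noise
around a condition-specific mean.  A selection round incubates the population
in one condition, gates on GFP (keep-high or keep-low, at an absolute
threshold or a quantile of the current population), sorts a fixed number of
passing cells, and regrows to the working population size by neutral
multinomial resampling.  Photoswitchable variants — GFP-high in the dark,
GFP-off in the light — survive both gate polarities and take over the
population, mirroring the screen's enrichment logic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VariantPhenotype",
    "GateSpec",
    "ScreenConfig",
    "ScreenTrajectory",
    "simulate_expression",
    "sort_round",
    "run_screen",
    "default_schedule",
    "light_only_schedule",
    "example_library",
]

DEFAULT_FLOOR = 10.0  # autofluorescence, arbitrary units
DEFAULT_CV = 0.6


@dataclass(frozen=True)
class VariantPhenotype:
    """Mean GFP in each condition plus log-normal cell-to-cell noise."""

    variant_id: str
    gfp_dark: float
    gfp_light: float
    noise_cv: float = DEFAULT_CV
    floor: float = DEFAULT_FLOOR

    def __post_init__(self) -> None:
        if self.noise_cv <= 0:
            raise ValueError("noise_cv must be > 0")
        if self.gfp_dark < 0 or self.gfp_light < 0:
            raise ValueError("expression means must be >= 0")

    def mean(self, condition: str) -> float:
        if condition == "dark":
            return self.gfp_dark
        if condition == "light":
            return self.gfp_light
        raise ValueError(f"condition must be dark|light, got {condition!r}")


@dataclass(frozen=True)
class GateSpec:
    """One sort: condition, polarity, and threshold (absolute or quantile)."""

    condition: str
    direction: str  # keep-high | keep-low
    quantile: float | None = 0.5
    threshold: float | None = None

    def __post_init__(self) -> None:
        if self.condition not in ("dark", "light"):
            raise ValueError(f"condition must be dark|light, got {self.condition!r}")
        if self.direction not in ("keep-high", "keep-low"):
            raise ValueError("direction must be keep-high|keep-low")
        if self.threshold is None:
            if self.quantile is None or not 0.0 < self.quantile < 1.0:
                raise ValueError("quantile must be in (0,1) when no threshold given")


def default_schedule(n_rounds: int = 3, quantile: float = 0.5) -> list[GateSpec]:
    """Alternating dark keep-high / light keep-low pairs (default 3 rounds).

    Each dark/light selection round recovers the GFP-positive population in
    the dark and then removes cells still GFP-positive under blue light.
    """
    gates: list[GateSpec] = []
    for _ in range(n_rounds):
        gates.append(GateSpec("dark", "keep-high", quantile=quantile))
        gates.append(GateSpec("light", "keep-low", quantile=quantile))
    return gates


def light_only_schedule(n_light: int = 3, quantile: float = 0.5) -> list[GateSpec]:
    """Single dark keep-high recovery followed by light keep-low sorts."""
    return [GateSpec("dark", "keep-high", quantile=quantile)] + [
        GateSpec("light", "keep-low", quantile=quantile) for _ in range(n_light)
    ]


@dataclass
class ScreenConfig:
    phenotypes: list[VariantPhenotype]
    frequencies: np.ndarray | None = None
    rounds: list[GateSpec] = field(default_factory=default_schedule)
    n_population: int = 500_000
    n_sorted: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        n = len(self.phenotypes)
        if n == 0:
            raise ValueError("no phenotypes")
        if self.frequencies is None:
            self.frequencies = np.full(n, 1.0 / n)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.frequencies.shape != (n,) or self.frequencies.min() < 0:
            raise ValueError("frequencies must be a nonnegative vector per phenotype")
        s = self.frequencies.sum()
        if not np.isclose(s, 1.0):
            raise ValueError(f"frequencies sum to {s}, expected 1")
        if self.n_sorted > self.n_population:
            raise ValueError("n_sorted must be <= n_population")


@dataclass
class ScreenTrajectory:
    """Per-round variant frequencies plus population GFP summaries."""

    variant_ids: list[str]
    frequencies: pd.DataFrame  # rows: round 0..R, columns: variant ids
    gfp_summary: pd.DataFrame  # rows: round, columns: median_dark, median_light

    def final_frequencies(self) -> pd.Series:
        return self.frequencies.iloc[-1]

    def top_variant(self) -> str:
        return str(self.final_frequencies().idxmax())


def simulate_expression(
    phenotype: VariantPhenotype, condition: str, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Single-cell GFP values: floor + log-normal(mean, CV) draws."""
    if n < 1:
        raise ValueError("n must be >= 1")
    m = phenotype.mean(condition)
    if m <= 0:
        return np.full(n, phenotype.floor)
    sigma2 = np.log1p(phenotype.noise_cv**2)
    mu = np.log(m) - sigma2 / 2.0
    return phenotype.floor + rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n)


def _population_expression(
    counts: np.ndarray,
    phenotypes: list[VariantPhenotype],
    condition: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Expression for counts[i] cells of each variant, concatenated per variant."""
    total = int(counts.sum())
    out = np.empty(total)
    means = np.array([ph.mean(condition) for ph in phenotypes])
    cvs = np.array([ph.noise_cv for ph in phenotypes])
    floors = np.array([ph.floor for ph in phenotypes])
    sigma2 = np.log1p(cvs**2)
    mu = np.where(means > 0, np.log(np.where(means > 0, means, 1.0)) - sigma2 / 2, 0.0)
    rep_mu = np.repeat(mu, counts)
    rep_sig = np.repeat(np.sqrt(sigma2), counts)
    rep_floor = np.repeat(floors, counts)
    rep_zero = np.repeat(means <= 0, counts)
    z = rng.standard_normal(total)
    out = rep_floor + np.exp(rep_mu + rep_sig * z)
    out[rep_zero] = rep_floor[rep_zero]
    return out


def sort_round(
    frequencies: np.ndarray,
    phenotypes: list[VariantPhenotype],
    gate: GateSpec,
    n_population: int,
    n_sorted: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """One FACS sort; returns the variant frequencies of the sorted cells.

    Cells are assigned to variants multinomially, expression is drawn under
    the gate's condition, the threshold is resolved (absolute or population
    quantile), and passing cells are subsampled without replacement down to
    ``n_sorted`` (multivariate hypergeometric over variants).
    """
    counts = rng.multinomial(n_population, frequencies)
    expr = _population_expression(counts, phenotypes, gate.condition, rng)
    if gate.threshold is not None:
        thr = gate.threshold
    else:
        thr = float(np.quantile(expr, gate.quantile))
    passing = expr > thr if gate.direction == "keep-high" else expr < thr

    # per-variant pass counts (expr is blocked by variant)
    edges = np.concatenate([[0], np.cumsum(counts)])
    pass_counts = np.array(
        [int(passing[edges[i] : edges[i + 1]].sum()) for i in range(len(counts))]
    )
    n_pass = int(pass_counts.sum())
    if n_pass == 0:
        raise RuntimeError(
            f"over-stringent gate: no cells pass {gate.direction} "
            f"{gate.condition} threshold {thr:.3g}"
        )
    if n_pass > n_sorted:
        sorted_counts = rng.multivariate_hypergeometric(pass_counts, n_sorted)
    else:
        sorted_counts = pass_counts
    return sorted_counts / sorted_counts.sum()


def run_screen(config: ScreenConfig) -> ScreenTrajectory:
    """Apply the gate schedule sequentially with multinomial regrowth.

    Deterministic given ``config.seed``.  Round 0 of the trajectory is the
    initial library; each subsequent row is the composition after one sort
    and regrowth.
    """
    rng = np.random.default_rng(config.seed)
    ids = [ph.variant_id for ph in config.phenotypes]
    freqs = config.frequencies.copy()

    freq_rows = [freqs.copy()]
    summaries = [_gfp_summary(freqs, config.phenotypes, config.n_population, rng)]
    for gate in config.rounds:
        freqs = sort_round(
            freqs, config.phenotypes, gate, config.n_population, config.n_sorted, rng
        )
        # neutral regrowth back to the working population size
        regrown = rng.multinomial(config.n_population, freqs)
        freqs = regrown / regrown.sum()
        freq_rows.append(freqs.copy())
        summaries.append(
            _gfp_summary(freqs, config.phenotypes, config.n_population, rng)
        )

    freq_df = pd.DataFrame(freq_rows, columns=ids)
    freq_df.index.name = "round"
    gfp_df = pd.DataFrame(summaries, columns=["median_dark", "median_light"])
    gfp_df.index.name = "round"
    return ScreenTrajectory(variant_ids=ids, frequencies=freq_df, gfp_summary=gfp_df)


def _gfp_summary(
    freqs: np.ndarray,
    phenotypes: list[VariantPhenotype],
    n_population: int,
    rng: np.random.Generator,
    n_sample: int = 10_000,
) -> tuple[float, float]:
    n = min(n_sample, n_population)
    counts = rng.multinomial(n, freqs)
    med = []
    for cond in ("dark", "light"):
        expr = _population_expression(counts, phenotypes, cond, rng)
        med.append(float(np.median(expr)))
    return med[0], med[1]


def example_library(
    n_dead: int = 1000,
    n_constitutive: int = 50,
    n_truncation: int = 20,
    n_photoswitchable: int = 1,
    floor: float = DEFAULT_FLOOR,
    cv: float = DEFAULT_CV,
) -> list[VariantPhenotype]:
    """The four phenotype classes seen in the starting library.

    Dead variants (out-of-frame or disruptive insertions) sit at the
    autofluorescence floor; truncation-like variants (insertions clipping some
    VP16 repeats of VP64) retain intermediate constitutive activity;
    constitutive variants are unperturbed in both conditions; the
    photoswitchable class is fully active in the dark and floor-level under
    blue light.
    """
    phenos: list[VariantPhenotype] = []
    for i in range(n_dead):
        phenos.append(VariantPhenotype(f"dead_{i}", floor, floor, cv, floor))
    for i in range(n_constitutive):
        phenos.append(VariantPhenotype(f"const_{i}", 3000.0, 3000.0, cv, floor))
    for i in range(n_truncation):
        phenos.append(VariantPhenotype(f"trunc_{i}", 300.0, 300.0, cv, floor))
    for i in range(n_photoswitchable):
        phenos.append(VariantPhenotype(f"photo_{i}", 3000.0, floor, cv, floor))
    return phenos
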