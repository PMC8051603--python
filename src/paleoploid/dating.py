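"""Two-step shared-event evolutionary-rate correction and WGD dating.

Lineages descended from a common polyploidy accumulate synonymous
substitutions at different rates, so the same event shows different Ks peaks
in different species.  The correction aligns each species' peak for a shared
event onto a reference species (step 1: the oldest shared event, e.g. the
eudicot-wide triplication, with the slowest genome as reference; step 2: a
younger shared duplication restricted to the clade that has it).  Corrected
peaks convert to ages via T = Ks / (2 r) with clock rate r in synonymous
substitutions per site per year.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence


@dataclass(frozen=True)
class CorrectionFactor:
    species: str
    event_basis: str  # label of the shared event the factor was derived from
    factor: float
    step: int = 1

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise ValueError("correction factor must be > 0")


@dataclass(frozen=True)
class DatingConfig:
    """Clock rate r (synonymous substitutions / site / year) and report style.

    There is deliberately no default rate: published rates differ several-fold
    between plant lineages, so the caller must choose one explicitly.
    """

    clock_rate: float
    report_interval: str = "mean±σ"

    def __post_init__(self) -> None:
        if self.clock_rate <= 0:
            raise ValueError("clock rate must be > 0")


def correction_factors(peak_means: Mapping[str, float], reference: str,
                       event: str = "shared", step: int = 1
                       ) -> dict[str, CorrectionFactor]:
    """Multiplicative factors f_s = mu_ref / mu_s aligning one shared event's
    peaks onto the reference species (f_ref = 1)."""
    if reference not in peak_means:
        raise ValueError(f"reference species {reference!r} not in peak means")
    if any(mu <= 0 for mu in peak_means.values()):
        raise ValueError("peak means must be positive")
    mu_ref = peak_means[reference]
    return {
        sp: CorrectionFactor(sp, event, mu_ref / mu, step)
        for sp, mu in peak_means.items()
    }


def net_factor(species: str, factors: Iterable[Mapping[str, CorrectionFactor]]
               ) -> float:
    """Compose per-step factor tables multiplicatively for one species.

    A species missing from a later step (e.g. a genome outside the clade the
    step-2 event is restricted to) takes factor 1 at that step.
    """
    f = 1.0
    seen = False
    for table in factors:
        if species in table:
            f *= table[species].factor
            seen = True
    if not seen:
        raise ValueError(f"no correction factor known for species {species!r}")
    return f


def apply_correction(ks_values: Sequence[float] | float,
                     factors: Iterable[Mapping[str, CorrectionFactor]],
                     species: str, species_b: str | None = None):
    """Scale Ks values (or a single peak mean) by the species' net factor.

    For an inter-species distribution pass both species: the scaling is the
    geometric mean of the two lineages' net factors.
    """
    tables = list(factors)
    f = net_factor(species, tables)
    if species_b is not None:
        f = (f * net_factor(species_b, tables)) ** 0.5
    if isinstance(ks_values, (int, float)):
        return float(ks_values) * f
    return [v * f for v in ks_values]


def relative_rates(peak_means: Mapping[str, float], reference: str
                   ) -> dict[str, float]:
    """Percent rate excess of each species over the reference, from one
    shared event's peak means: (mu_s / mu_ref - 1) x 100."""
    if reference not in peak_means:
        raise ValueError(f"reference species {reference!r} not in peak means")
    mu_ref = peak_means[reference]
    if mu_ref <= 0 or any(mu <= 0 for mu in peak_means.values()):
        raise ValueError("peak means must be positive")
    return {sp: (mu / mu_ref - 1.0) * 100.0 for sp, mu in peak_means.items()}


def date_event(mu: float, sigma: float, config: DatingConfig
               ) -> tuple[float, float, float]:
    """Convert a corrected Ks peak (mu, sigma) to an age interval in Mya.

    T = mu / (2 r); the interval is [(mu - sigma), (mu + sigma)] / (2 r),
    clipped at zero.
    """
    if mu < 0:
        raise ValueError("peak mean must be >= 0")
    denom = 2.0 * config.clock_rate * 1e6  # years -> Mya
    mid = mu / denom
    lo = max(0.0, (mu - sigma)) / denom
    hi = (mu + sigma) / denom
    return lo, mid, hi


def write_dating_report(rows: Iterable[tuple], path) -> None:
    """Rows: (event, species, mu_raw, mu_corrected, sigma, t_low, t_mid, t_high)."""
    with open(path, "w") as fh:
        fh.write("event\tspecies\tmu_raw\tmu_corrected\tsigma\tT_low\tT_mid\tT_high\n")
        for r in rows:
            fh.write("\t".join(f"{v:.6g}" if isinstance(v, float) else str(v)
                               for v in r) + "\n")
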