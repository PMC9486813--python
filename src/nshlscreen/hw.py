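"""Hardy-Weinberg projection of autosomal-recessive disease frequency.

For a recessive gene with combined pathogenic allele frequency q, random
mating puts the affected-genotype frequency at q^2. Because pathogenic allele
frequencies here are small, the carrier relation 2pq is used with the p~1
approximation, so q = carrier_frequency / 2. Since q is the *combined* allele
frequency over all of a gene's P/LP alleles, q^2 implicitly counts compound
heterozygotes as affected, which is the intended interpretation for a
recessive locus with allelic heterogeneity.

An exact mode (solving 2q(1-q) = carrier frequency for q) is available for
sensitivity analysis; it is not the default behavior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

from .cohort import round_half_up


class HwError(ValueError):
    """Raised on out-of-range allele or carrier frequencies."""


@dataclass(frozen=True)
class HwEstimate:
    """Per-gene Hardy-Weinberg projection."""

    gene_symbol: str
    q: float
    q_squared: float

    @property
    def per_1000(self) -> float:
        """Affected frequency per 1,000 people, rounded to 2 decimals."""
        return round_half_up(self.q_squared * 1000.0, 2)

    @property
    def one_in_x(self) -> int | None:
        """Affected frequency as 1-in-X (nearest integer); None when q = 0."""
        if self.q_squared == 0:
            return None
        return int(round_half_up(1.0 / self.q_squared, 0))


def carrier_to_q(carrier_frequency: float, exact: bool = False) -> float:
    """Allele frequency q from a carrier (heterozygote) frequency.

    Default is the p~1 approximation q = cf / 2; ``exact=True`` solves the
    full Hardy-Weinberg relation 2q(1-q) = cf (smaller root).
    """
    if not 0.0 <= carrier_frequency <= 1.0:
        raise HwError(f"carrier frequency {carrier_frequency} outside [0, 1]")
    if not exact:
        return carrier_frequency / 2.0
    # 2q^2 - 2q + cf = 0 -> q = (1 - sqrt(1 - 2 cf)) / 2
    if carrier_frequency > 0.5:
        raise HwError("exact mode requires carrier frequency <= 0.5")
    return (1.0 - math.sqrt(1.0 - 2.0 * carrier_frequency)) / 2.0


def hw_affected_frequency(q: float, gene_symbol: str = "") -> HwEstimate:
    """Project the affected-individual frequency q^2 from allele frequency q."""
    if not 0.0 <= q <= 1.0:
        raise HwError(f"allele frequency {q} outside [0, 1]")
    return HwEstimate(gene_symbol=gene_symbol, q=q, q_squared=q * q)


def combined_recessive_burden(
    estimates: Iterable[HwEstimate],
    gene_modes: dict[str, set[str]] | None = None,
) -> tuple[float, int | None]:
    """Total recessive disease burden over a set of gene estimates.

    Sums q^2 across genes and reports (per-1,000, 1-in-X). When
    ``gene_modes`` is given, every estimate's gene must carry an AR mode;
    AD-exclusive genes are a contract violation, since a dominant-only gene
    has no biallelic disease class to project.
    """
    total = 0.0
    for est in estimates:
        if gene_modes is not None:
            modes = gene_modes.get(est.gene_symbol)
            if modes is None:
                raise HwError(f"gene {est.gene_symbol} has no recorded modes")
            if "AR" not in modes:
                raise HwError(
                    f"gene {est.gene_symbol} is not autosomal recessive "
                    f"(modes: {sorted(modes)})"
                )
        total += est.q_squared
    per_1000 = round_half_up(total * 1000.0, 2)
    one_in_x = int(round_half_up(1.0 / total, 0)) if total > 0 else None
    return per_1000, one_in_x
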