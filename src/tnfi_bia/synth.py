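"""Synthetic payer-market generator with analytic ground truth.

Emulates the structure the real reimbursement series show: a flat unit price
before biosimilar entry, multiplicative price decay from the entry year on
(the entry-year price is already reduced, as observed in practice), steady
multiplicative volume growth, and a biosimilar share that takes over the
market linearly.  Multiplicative lognormal noise (mean 1) perturbs price and
volume independently, preserving positivity.

Defaults mirror the infliximab all-indications trajectory: 4.80 EUR/mg before
entry, 21%/year price decay from 2014, ~0.96M mg growing 20%/year, ~1540 mg
per patient-year; with those settings the unit cost falls to ~15% of the
reference by the ninth year.

:func:`expected_estimated_savings` gives the noise-free expectation of the
actual-volume estimated-savings model in closed form, so parameter recovery
by the savings engine can be checked exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import RecordValidationError
from .records import (AnnualDrugRecord, CurrencyRate, DrugMeta, Product,
                      RecordSet, Sector)

__all__ = [
    "MarketScenarioConfig",
    "generate_series",
    "expected_estimated_savings",
    "biosimilar_share",
    "product_spend",
    "ground_truth",
]


@dataclass(frozen=True)
class MarketScenarioConfig:
    """Parameters of one synthetic drug market."""

    drug: str = "SYN"
    years: tuple[int, int] = (2013, 2021)   # inclusive span
    entry_year: int = 2014                  # first biosimilar year
    p0: float = 4.80                        # pre-entry unit price, EUR/mg
    price_decay: float = 0.79               # per-year multiplicative factor after entry
    v0: float = 960_000.0                   # baseline annual volume, mg
    volume_growth: float = 1.20             # per-year multiplicative factor
    patients0: int = 620                    # baseline patient count (implied by dose)
    dose_per_patient: float = 1540.0        # mean annual mg per patient
    share_takeover: float = 0.30            # per-year biosimilar share gain
    noise_cv: float = 0.05                  # CV of lognormal noise on price & volume
    seed: int = 0
    population: float = 38_000_000.0

    def __post_init__(self) -> None:
        start, end = self.years
        if end < start:
            raise RecordValidationError(f"invalid year span {self.years}")
        if not (start <= self.entry_year <= end + 1):
            raise RecordValidationError(
                f"entry_year {self.entry_year} outside span {self.years}")
        if not self.p0 > 0:
            raise RecordValidationError("p0 must be positive")
        if not 0 < self.price_decay <= 1:
            raise RecordValidationError("price_decay must be in (0, 1]")
        if not self.v0 > 0:
            raise RecordValidationError("v0 must be positive")
        if not 0 <= self.share_takeover <= 1:
            raise RecordValidationError("share_takeover must be in [0, 1]")
        if self.noise_cv < 0:
            raise RecordValidationError("noise_cv must be >= 0")
        if not self.dose_per_patient > 0:
            raise RecordValidationError("dose_per_patient must be positive")

    # -- noise-free structural paths ----------------------------------------

    def unit_price(self, year: int) -> float:
        """Noise-free unit price: p0 * decay^max(0, year - entry + 1)."""
        return self.p0 * self.price_decay ** max(0, year - self.entry_year + 1)

    def volume(self, year: int) -> float:
        """Noise-free annual volume: v0 * growth^(year - start)."""
        return self.v0 * self.volume_growth ** (year - self.years[0])


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Mean-1 multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(n)
    sigma2 = math.log(1.0 + cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=n)


def generate_series(config: MarketScenarioConfig) -> RecordSet:
    """Generate a RecordSet for one synthetic drug market (ALL sector).

    Reported volume and unit price each carry independent lognormal noise;
    reimbursement is their product, and patients are volume over the mean
    annual dose, rounded.  Deterministic given ``config.seed``.
    """
    start, end = config.years
    years = range(start, end + 1)
    n = end - start + 1
    rng = np.random.default_rng(config.seed)
    price_noise = _lognormal_factors(rng, config.noise_cv, n)
    volume_noise = _lognormal_factors(rng, config.noise_cv, n)
    records = []
    for i, year in enumerate(years):
        price = config.unit_price(year) * price_noise[i]
        volume = config.volume(year) * volume_noise[i]
        records.append(AnnualDrugRecord(
            drug=config.drug, year=year, sector=Sector.ALL,
            mg_volume=volume,
            reimbursement_value=price * volume,
            patients=int(round(volume / config.dose_per_patient)),
        ))
    meta = DrugMeta(
        drug=config.drug,
        first_biosimilar_year=config.entry_year,
        # WHO-style DDD: mean maintenance dose per day
        ddd_mg=config.dose_per_patient / 365.0,
        products=(Product(f"{config.drug}-REF", False, start, end),
                  Product(f"{config.drug}-BIOSIM", True, config.entry_year, end)),
        name="synthetic market scenario",
    )
    return RecordSet(records=records, meta={config.drug: meta},
                     population=config.population, currency=CurrencyRate(1.0),
                     version=f"synthetic seed={config.seed}")


def expected_estimated_savings(config: MarketScenarioConfig) -> float:
    """Closed-form noise-free estimated savings (actual-volume model).

    The model's expectation is ``sum_{t > ref} V_t * (p0 - p_t)`` with the
    reference year entry_year - 1.  With ``g`` the volume growth, ``d`` the
    price decay and ``K`` post-entry years this is the difference of two
    geometric sums::

        p0 * v0 * g^(entry-start) * [ S(g, K) - d * S(g*d, K) ]
        where S(x, K) = (x^K - 1)/(x - 1), S(1, K) = K.
    """
    start, end = config.years
    K = end - config.entry_year + 1
    if K <= 0:
        return 0.0
    g, d = config.volume_growth, config.price_decay

    def geom(x: float, k: int) -> float:
        return float(k) if math.isclose(x, 1.0) else (x ** k - 1.0) / (x - 1.0)

    lead = config.p0 * config.v0 * g ** (config.entry_year - start)
    return lead * (geom(g, K) - d * geom(g * d, K))


def biosimilar_share(config: MarketScenarioConfig, year: int) -> float:
    """Biosimilar share of spend: 0 before entry, then takeover per year, capped at 1."""
    if year < config.entry_year:
        return 0.0
    return min(1.0, config.share_takeover * (year - config.entry_year + 1))


def product_spend(config: MarketScenarioConfig,
                  recordset: RecordSet | None = None,
                  ) -> dict[tuple[str, int], float]:
    """Split each year's reimbursement between the reference product and the
    biosimilar according to the configured share path.

    When ``recordset`` is omitted a fresh (seeded) one is generated.
    """
    rs = recordset if recordset is not None else generate_series(config)
    spend: dict[tuple[str, int], float] = {}
    for rec in rs.records:
        share = biosimilar_share(config, rec.year)
        spend[(f"{config.drug}-REF", rec.year)] = rec.reimbursement_value * (1 - share)
        if share > 0:
            spend[(f"{config.drug}-BIOSIM", rec.year)] = rec.reimbursement_value * share
    return spend


def ground_truth(config: MarketScenarioConfig) -> dict:
    """JSON-serialisable ground truth for a scenario: true price/volume paths,
    expected estimated savings and the biosimilar share path."""
    start, end = config.years
    years = list(range(start, end + 1))
    return {
        "drug": config.drug,
        "reference_year": config.entry_year - 1,
        "expected_estimated_savings_eur": expected_estimated_savings(config),
        "unit_price_path": {y: config.unit_price(y) for y in years},
        "volume_path": {y: config.volume(y) for y in years},
        "biosimilar_share_path": {y: biosimilar_share(config, y) for y in years},
    }
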