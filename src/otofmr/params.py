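"""Isotope-system parameters and their uncertainty ranges.

Central values and 95% confidence ranges for every quantity entering the
temperature and C_resp mass-balance equations: the aragonite thermometry
coefficients, the carbon end-members (diet, dissolved inorganic carbon),
ambient-water oxygen composition by origin, analytical measurement
uncertainty on the otolith values themselves, and the oceanic Suess-effect
drift used to standardise d13C to a common reference year.

All delta values are per-mil (‰) on the VPDB scale.  Confidence-interval
fields are FULL 95% widths; converting a width to a normal standard
deviation uses the divisor in :class:`McConfig` (default 3.92 = 2 x 1.96).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace


@dataclass(frozen=True)
class ThermometryParams:
    """Linear aragonite-thermometry relationship d18O_oto - d18O_water = a + b*T.

    Parameters
    ----------
    intercept_a : float
        Intercept ``a`` in ‰ (default 5.193).
    slope_b : float
        Slope ``b`` in ‰ per °C (default -0.27); must be non-zero.
    ci_a, ci_b : float
        Full 95% confidence widths of the two coefficients.
    """

    intercept_a: float = 5.193
    slope_b: float = -0.27
    ci_a: float = 0.12
    ci_b: float = 0.016

    def __post_init__(self) -> None:
        if self.slope_b == 0:
            raise ValueError("thermometry slope_b must be non-zero")
        if self.ci_a < 0 or self.ci_b < 0:
            raise ValueError("confidence widths must be non-negative")


@dataclass(frozen=True)
class CarbonParams:
    """Carbon mass-balance end-members, water d18O by origin, and Suess drift.

    ``d13C_diet`` and ``d13C_DIC`` are the two carbon sources mixing into
    otolith aragonite; they must be isotopically distinct.  ``epsilon_frac``
    is the total diet-to-otolith fractionation, zero by default.  The Suess
    correction standardises measured d13C_oto to ``suess_ref_year`` at
    ``suess_rate`` ‰ per year of the fish's birth.
    """

    d13C_diet: float = -18.5
    d13C_DIC: float = 1.0
    d18O_water_west: float = 1.0
    d18O_water_med: float = 1.2
    ci_d13C_diet: float = 1.0
    ci_d13C_DIC: float = 0.5
    ci_d18O_water: float = 0.2
    ci_d13C_oto: float = 0.4
    ci_d18O_oto: float = 0.1
    epsilon_frac: float = 0.0
    suess_rate: float = -0.025
    suess_ref_year: int = 2019

    def __post_init__(self) -> None:
        if not self.d13C_diet < self.d13C_DIC:
            raise ValueError(
                "d13C_diet must be lower than d13C_DIC "
                "(carbon sources must be isotopically distinct)"
            )
        for f in fields(self):
            if f.name.startswith("ci_") and getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be non-negative")

    def water_for_origin(self, origin: str) -> float:
        """Central ambient-water d18O (‰) for a fish origin.

        ``west`` (western North Atlantic / Gulf of Mexico) and ``med``
        (Mediterranean) have distinct defaults; ``unknown`` raises unless a
        caller supplies its own default.
        """
        if origin == "west":
            return self.d18O_water_west
        if origin == "med":
            return self.d18O_water_med
        raise KeyError(f"no d18O_water value for origin {origin!r}")


@dataclass(frozen=True)
class McConfig:
    """Monte-Carlo propagation settings.

    ``n_replicates`` noisy replicates are drawn (replicate index 0 is
    reserved for the central, noise-free pass).  ``width_to_sd`` converts a
    full 95% width to a normal standard deviation.  ``shared_coefficients``
    draws one thermometry (a, b) pair per replicate, applied to every fish;
    set False to redraw per fish.  ``per_fish_sources`` redraws the diet /
    DIC / water end-members per fish within a replicate; set False to draw
    them once per replicate.
    """

    n_replicates: int = 100
    seed: int = 0
    ci_level: float = 0.95
    width_to_sd: float = 3.92
    shared_coefficients: bool = True
    per_fish_sources: bool = True

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must lie in (0, 1)")
        if self.width_to_sd <= 0:
            raise ValueError("width_to_sd must be positive")


@dataclass(frozen=True)
class ParameterSet:
    """Bundle of thermometry + carbon parameters used by the pipeline."""

    thermometry: ThermometryParams = field(default_factory=ThermometryParams)
    carbon: CarbonParams = field(default_factory=CarbonParams)

    def with_overrides(self, **kwargs: float) -> "ParameterSet":
        """Return a copy with named fields replaced on whichever sub-object owns them."""
        therm_fields = {f.name for f in fields(ThermometryParams)}
        carbon_fields = {f.name for f in fields(CarbonParams)}
        t_kw = {k: v for k, v in kwargs.items() if k in therm_fields}
        c_kw = {k: v for k, v in kwargs.items() if k in carbon_fields}
        unknown = set(kwargs) - therm_fields - carbon_fields
        if unknown:
            raise TypeError(f"unknown parameter overrides: {sorted(unknown)}")
        return ParameterSet(
            thermometry=replace(self.thermometry, **t_kw),
            carbon=replace(self.carbon, **c_kw),
        )
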