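"""Chemical and kinetic data model for covalent aldehyde sensing.

A single engineered cysteine inside an alpha-hemolysin pore reacts reversibly
with free (non-hydrated) aldehyde to form a hemithioacetal adduct.  The adduct
partially blocks the ionic current; its residual level identifies the analyte
and the event kinetics quantify it.  The model used throughout the package:

* association is bimolecular in the *total* aldehyde concentration,
  ``v_on = k_on * C_tot``, equivalently ``v_on = k_on' * C_free`` with the
  hydration-corrected rate constant ``k_on' = k_on * (1 + K_hyd)``;
* dissociation is unimolecular and concentration independent,
  ``v_off = k_off``;
* the hydration equilibrium ``K_hyd = [hydrate]/[free aldehyde]`` removes a
  fraction ``K_hyd/(1+K_hyd)`` of the analyte from the thiol-reactive pool.

Units: concentrations in mM, rate constants in mM^-1 s^-1 (association) and
s^-1 (dissociation), currents in pA, residual levels as percent of the open
pore current (I_res% = I_res / I_P x 100, a positive number because the two
currents share a sign).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ValidationError",
    "ConfigError",
    "DiastereomerSpec",
    "AnalyteSpec",
    "PoreSpec",
    "MixtureSpec",
    "free_fraction",
    "correct_kon",
    "khyd_from_nmr",
    "expected_on_rate",
    "mean_adduct_lifetime",
    "apply_oxidation",
]

_FRACTION_TOL = 1e-9


class ValidationError(ValueError):
    """An input violates a documented precondition."""


class ConfigError(ValueError):
    """A configuration (fixture, scenario, idealization) is inconsistent."""


@dataclass(frozen=True)
class DiastereomerSpec:
    """One stereochemical form of the hemithioacetal adduct.

    Parameters
    ----------
    label : str
        ``"A"`` or ``"B"``; by convention A has the larger residual level.
    ires_pct : float
        Residual current during the blockade, percent of the open-pore
        current, in ``(0, 100]``.
    k_off : float
        Dissociation rate constant, s^-1.
    fraction : float
        Probability that a formation event yields this diastereomer.
    """

    label: str
    ires_pct: float
    k_off: float
    fraction: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.ires_pct <= 100.0):
            raise ValidationError(
                f"ires_pct must be in (0, 100], got {self.ires_pct!r}")
        if not self.k_off > 0.0:
            raise ValidationError(f"k_off must be > 0, got {self.k_off!r}")
        if not (0.0 <= self.fraction <= 1.0):
            raise ValidationError(
                f"fraction must be in [0, 1], got {self.fraction!r}")


@dataclass(frozen=True)
class AnalyteSpec:
    """One aldehyde species and its sensing parameters.

    ``k_on_obs`` is the observed association rate constant against total
    aldehyde (mM^-1 s^-1); ``khyd`` the hydration equilibrium constant.
    """

    name: str
    khyd: float
    k_on_obs: float
    diastereomers: tuple[DiastereomerSpec, ...]

    def __post_init__(self) -> None:
        if self.khyd < 0.0:
            raise ValidationError(f"khyd must be >= 0, got {self.khyd!r}")
        if self.k_on_obs < 0.0:
            raise ValidationError(
                f"k_on_obs must be >= 0, got {self.k_on_obs!r}")
        dias = tuple(self.diastereomers)
        if not dias:
            raise ValidationError(f"{self.name}: needs >= 1 diastereomer")
        object.__setattr__(self, "diastereomers", dias)
        total = sum(d.fraction for d in dias)
        if abs(total - 1.0) > _FRACTION_TOL:
            raise ValidationError(
                f"{self.name}: diastereomer fractions sum to {total}, not 1")
        if len(dias) == 2:
            by_label = {d.label: d for d in dias}
            if set(by_label) == {"A", "B"} and (
                    by_label["A"].ires_pct < by_label["B"].ires_pct):
                raise ValidationError(
                    f"{self.name}: diastereomer A must have the larger "
                    "ires_pct (convention)")

    @property
    def k_on_prime(self) -> float:
        """Hydration-corrected association rate constant (mM^-1 s^-1)."""
        return correct_kon(self.k_on_obs, self.khyd)

    @property
    def levels(self) -> tuple[float, ...]:
        return tuple(d.ires_pct for d in self.diastereomers)


@dataclass(frozen=True)
class PoreSpec:
    """An engineered heteroheptameric pore and its recording baseline.

    ``open_current`` (I_P, pA) is signed: about -129 pA at -50 mV for the
    reference (AG)6(AG-T115C) variant.  ``rms_noise`` is the per-sample
    baseline noise (pA) after the acquisition filter.  ``level_jitter_pct``
    is the event-to-event spread of the adduct level (SD, in ires% units):
    white sample noise averages away over long events, but the measured
    per-event level spread does not, so slow level fluctuations are modeled
    as one Gaussian offset per blockade.
    """

    name: str
    open_current: float
    potential: float
    rms_noise: float
    level_jitter_pct: float = 0.05

    def __post_init__(self) -> None:
        if self.open_current == 0.0:
            raise ValidationError("open_current must be nonzero")
        if self.rms_noise < 0.0:
            raise ValidationError("rms_noise must be >= 0")
        if self.level_jitter_pct < 0.0:
            raise ValidationError("level_jitter_pct must be >= 0")


@dataclass(frozen=True)
class MixtureSpec:
    """Analyte mixture in the trans chamber.

    ``components`` maps aldehydes to total concentrations (mM).
    ``alcohols`` are placeholders for species invisible to the thiol until
    enzymatic oxidation converts them to their target aldehyde: tuples of
    (alcohol name, target AnalyteSpec or None, concentration mM).
    """

    components: tuple[tuple[AnalyteSpec, float], ...]
    alcohols: tuple[tuple[str, AnalyteSpec | None, float], ...] = ()

    def __post_init__(self) -> None:
        comps = tuple(self.components)
        object.__setattr__(self, "components", comps)
        object.__setattr__(self, "alcohols", tuple(self.alcohols))
        names = [a.name for a, _ in comps]
        if len(set(names)) != len(names):
            raise ValidationError(f"duplicate analyte names: {names}")
        for analyte, conc in comps:
            if conc < 0.0:
                raise ValidationError(
                    f"{analyte.name}: concentration must be >= 0, got {conc}")
        for name, _, conc in self.alcohols:
            if conc < 0.0:
                raise ValidationError(
                    f"{name}: concentration must be >= 0, got {conc}")

    def concentration(self, name: str) -> float:
        for analyte, conc in self.components:
            if analyte.name == name:
                return conc
        raise KeyError(name)

    @property
    def analytes(self) -> tuple[AnalyteSpec, ...]:
        return tuple(a for a, _ in self.components)


def free_fraction(analyte: AnalyteSpec, total_conc: float) -> float:
    """Free (thiol-reactive) aldehyde concentration, mM.

    The hydrate is unreactive, so ``C_free = C_tot / (1 + K_hyd)``.
    """
    if total_conc < 0.0:
        raise ValidationError(f"total_conc must be >= 0, got {total_conc}")
    return total_conc / (1.0 + analyte.khyd)


def correct_kon(k_on_obs: float, khyd: float) -> float:
    """Hydration-corrected association rate constant k_on' (mM^-1 s^-1)."""
    if k_on_obs < 0.0 or khyd < 0.0:
        raise ValidationError("k_on_obs and khyd must be >= 0")
    return k_on_obs * (1.0 + khyd)


def khyd_from_nmr(integral_ald: float, integral_hyd: float) -> float:
    """Hydration constant from 1H-NMR peak integrals of the two forms."""
    if integral_ald <= 0.0:
        raise ValidationError(
            "aldehyde integral must be > 0 (ratio undefined)")
    if integral_hyd < 0.0:
        raise ValidationError("hydrate integral must be >= 0")
    return integral_hyd / integral_ald


def expected_on_rate(analyte: AnalyteSpec, total_conc: float) -> float:
    """Adduct-formation rate v_on (s^-1) at a total concentration (mM)."""
    if total_conc < 0.0:
        raise ValidationError(f"total_conc must be >= 0, got {total_conc}")
    return analyte.k_on_obs * total_conc


def mean_adduct_lifetime(analyte: AnalyteSpec) -> float:
    """Mean blockade duration (s): sum of fraction_d / k_off_d."""
    return sum(d.fraction / d.k_off for d in analyte.diastereomers)


def apply_oxidation(mixture: MixtureSpec) -> MixtureSpec:
    """Convert every alcohol placeholder into its target aldehyde.

    Models treatment with an engineered alcohol oxidase: each alcohol becomes
    its aldehyde at the same concentration (molar amount conserved); existing
    aldehyde components are untouched; the returned mixture carries no
    alcohols.
    """
    concs: dict[str, float] = {}
    specs: dict[str, AnalyteSpec] = {}
    for analyte, conc in mixture.components:
        specs[analyte.name] = analyte
        concs[analyte.name] = concs.get(analyte.name, 0.0) + conc
    for name, target, conc in mixture.alcohols:
        if target is None:
            raise ConfigError(
                f"alcohol {name!r} has no target aldehyde configured")
        specs[target.name] = target
        concs[target.name] = concs.get(target.name, 0.0) + conc
    return MixtureSpec(
        components=tuple((specs[n], concs[n]) for n in concs), alcohols=())
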