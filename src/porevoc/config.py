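"""Loading of pore/analyte parameter files and packaged fixtures.

Fixture files are YAML with one ``pore`` block and a list of ``analytes``;
every numeric value carries a provenance flag (``printed`` from the source
measurements, ``interpolated``, or ``derived``).  Provenance is kept as
metadata and never interpreted by the code.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

from .analytes import (
    AnalyteSpec,
    ConfigError,
    DiastereomerSpec,
    MixtureSpec,
    PoreSpec,
)

__all__ = ["Fixture", "available_fixtures", "load_fixture", "load_mixture",
           "load_scenario", "scenario_from_dict"]

_FIXTURE_PKG = "porevoc.fixtures"


@dataclass(frozen=True)
class Fixture:
    """A pore variant plus the analytes characterised with it."""

    pore: PoreSpec
    analytes: dict[str, AnalyteSpec]
    provenance: dict[str, Any]

    def analyte(self, name: str) -> AnalyteSpec:
        try:
            return self.analytes[name]
        except KeyError:
            raise ConfigError(
                f"analyte {name!r} not in fixture {self.pore.name!r}; "
                f"known: {sorted(self.analytes)}") from None

    def mixture(self, concentrations: Mapping[str, float]) -> MixtureSpec:
        """Build a mixture of fixture analytes at given concentrations (mM)."""
        return MixtureSpec(components=tuple(
            (self.analyte(name), float(conc))
            for name, conc in concentrations.items()))

    @property
    def levels(self) -> tuple[float, ...]:
        """All configured adduct residual levels (ires %), sorted."""
        out: list[float] = []
        for spec in self.analytes.values():
            out.extend(spec.levels)
        return tuple(sorted(out))


def available_fixtures() -> list[str]:
    files = resources.files(_FIXTURE_PKG)
    return sorted(
        p.name[:-5] for p in files.iterdir() if p.name.endswith(".yaml"))


def _parse_analyte(entry: Mapping[str, Any]) -> AnalyteSpec:
    try:
        dias = tuple(
            DiastereomerSpec(
                label=str(d["label"]),
                ires_pct=float(d["ires_pct"]),
                k_off=float(d["k_off"]),
                fraction=float(d.get("fraction", 1.0)),
            )
            for d in entry["diastereomers"])
        return AnalyteSpec(
            name=str(entry["name"]),
            khyd=float(entry["khyd"]),
            k_on_obs=float(entry["k_on_obs"]),
            diastereomers=dias,
        )
    except KeyError as exc:
        raise ConfigError(f"analyte entry missing field {exc}") from None


def _parse_fixture(doc: Mapping[str, Any]) -> Fixture:
    if "pore" not in doc or "analytes" not in doc:
        raise ConfigError("fixture file needs 'pore' and 'analytes' blocks")
    p = doc["pore"]
    pore = PoreSpec(
        name=str(p["name"]),
        open_current=float(p["open_current_pa"]),
        potential=float(p["potential_mv"]),
        rms_noise=float(p["rms_noise_pa"]),
        level_jitter_pct=float(p.get("level_jitter_pct", 0.05)),
    )
    analytes = {}
    provenance: dict[str, Any] = {"pore": p.get("provenance", {})}
    for entry in doc["analytes"]:
        spec = _parse_analyte(entry)
        analytes[spec.name] = spec
        provenance[spec.name] = entry.get("provenance", {})
    return Fixture(pore=pore, analytes=analytes, provenance=provenance)


def load_fixture(name_or_path: str | Path) -> Fixture:
    """Load a packaged fixture by short name, or any fixture YAML by path."""
    path = Path(name_or_path)
    if path.suffix in {".yaml", ".yml"} or path.exists():
        text = path.read_text()
    else:
        ref = resources.files(_FIXTURE_PKG) / f"{name_or_path}.yaml"
        try:
            text = ref.read_text()
        except FileNotFoundError:
            raise ConfigError(
                f"unknown fixture {name_or_path!r}; packaged fixtures: "
                f"{available_fixtures()}") from None
    doc = yaml.safe_load(text)
    return _parse_fixture(doc)


def load_mixture(fixture: Fixture, spec: Mapping[str, Any]) -> MixtureSpec:
    """Build a MixtureSpec from a config mapping.

    ``spec`` maps analyte names to concentrations (mM); an optional
    ``alcohols`` key holds entries ``{name, target, concentration_mm}`` for
    species that only become visible after enzymatic oxidation.
    """
    plain = {k: v for k, v in spec.items() if k != "alcohols"}
    components = tuple(
        (fixture.analyte(name), float(conc)) for name, conc in plain.items())
    alcohols = tuple(
        (str(a["name"]),
         fixture.analyte(a["target"]) if a.get("target") else None,
         float(a["concentration_mm"]))
        for a in spec.get("alcohols", ()))
    return MixtureSpec(components=components, alcohols=alcohols)


def scenario_from_dict(doc: Mapping[str, Any], seed: int | None = None):
    """Build a SimulationScenario from a config mapping.

    Schema::

        fixture: ag_t115c          # packaged name or a YAML path
        seed: 7
        sampling_rate_hz: 50000    # optional
        filter_cutoff_hz: 10000    # optional
        pore: {rms_noise_pa: 1.0}  # optional field overrides
        segments:
          - duration_s: 600
            mixture: {butanal: 3.0}
    """
    from dataclasses import replace as dc_replace

    from .simulate import Segment, SimulationScenario

    if "fixture" not in doc or "segments" not in doc:
        raise ConfigError("scenario needs 'fixture' and 'segments'")
    fixture = load_fixture(doc["fixture"])
    pore = fixture.pore
    overrides = doc.get("pore", {})
    if overrides:
        rename = {"open_current_pa": "open_current",
                  "potential_mv": "potential", "rms_noise_pa": "rms_noise",
                  "level_jitter_pct": "level_jitter_pct", "name": "name"}
        pore = dc_replace(pore, **{
            rename[k]: v for k, v in overrides.items() if k in rename})
    segments = tuple(
        Segment(duration=float(seg["duration_s"]),
                mixture=load_mixture(fixture, seg["mixture"]))
        for seg in doc["segments"])
    return SimulationScenario(
        pore=pore,
        segments=segments,
        sampling_rate=float(doc.get("sampling_rate_hz", 50_000.0)),
        filter_cutoff=float(doc.get("filter_cutoff_hz", 10_000.0)),
        seed=int(doc.get("seed", 0) if seed is None else seed),
    )


def load_scenario(path: str | Path, seed: int | None = None):
    doc = yaml.safe_load(Path(path).read_text())
    return scenario_from_dict(doc, seed=seed)
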