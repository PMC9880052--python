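"""Named mutant parameter presets for the in-silico mouse lines.

Each preset is a small override map applied to a wild-type parameter set:

* ``RGS9_0.2x / RGS9_2x / RGS9_4x`` — RGS9 complex expression scaled.
* ``RK_0.3x`` — hemizygous rhodopsin-kinase knockout; all per-state
  phosphorylation rates reduced 3-fold.
* ``RK_S561L`` — membrane-tethered mutant kinase over a WT background;
  phosphorylation rates increased 3-fold.
* ``GCAP2_KO`` — maximal low-Ca2+ cyclase rate drops to 40% of WT and the
  remaining (GCAP1) activity has a Ca2+ K_1/2 of 47 nM.
* ``GCAPs_KO`` — both GCAPs removed: the cyclase rate is frozen at the
  wild-type dark value, so the dark current is preserved but all Ca2+
  feedback onto synthesis is gone.
* ``CNG_CaM_null`` — channel lacking the calmodulin site; its cGMP
  affinity is pinned at the low-Ca2+ value K_cG_min.
* ``PDE_0.1x / PDE_10x`` — effector (PDE subunit) expression scaled;
  basal hydrolysis capacity k_hyd * E_tot scales along with it.
* ``Rec_KO`` — recoverin knockout: the free-RK fraction is 1 at every
  Ca2+ (implemented as Rec_tot = 0).

Preset definitions are shipped as a data file (``data/presets.yaml``) so
that custom variants can be added without touching code.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field as dc_field
from typing import Any, Mapping

import yaml

from . import equilibria
from .parameters import Params
from .rate_laws import cyclase_rate

__all__ = ["MutantPreset", "PRESET_NAMES", "get_preset", "apply_preset"]


@dataclass(frozen=True)
class MutantPreset:
    """A parameter override map: multiplicative scales and replacements."""

    name: str
    scales: Mapping[str, float] = dc_field(default_factory=dict)
    sets: Mapping[str, Any] = dc_field(default_factory=dict)
    freeze_cyclase_dark: bool = False  # GCAPs knockout semantics

    def inverse_of(self, original: Params) -> "MutantPreset":
        """Preset that undoes this one when applied to the mutated Params."""
        inv_scales = {k: 1.0 / v for k, v in self.scales.items()}
        inv_sets = {k: getattr(original, k) for k in self.sets}
        if self.freeze_cyclase_dark:
            inv_sets["alpha_freeze"] = original.alpha_freeze
        return MutantPreset(
            name=f"inverse({self.name})", scales=inv_scales, sets=inv_sets
        )


def _load_preset_table() -> dict[str, MutantPreset]:
    ref = importlib.resources.files("rodcascade.data") / "presets.yaml"
    with importlib.resources.as_file(ref) as path:
        with open(path) as fh:
            doc = yaml.safe_load(fh)
    table: dict[str, MutantPreset] = {}
    for name, spec in doc.items():
        spec = spec or {}
        table[name] = MutantPreset(
            name=name,
            scales=dict(spec.get("scale", {})),
            sets=dict(spec.get("set", {})),
            freeze_cyclase_dark=bool(spec.get("freeze_cyclase_dark", False)),
        )
    return table


_PRESETS = _load_preset_table()
PRESET_NAMES = tuple(_PRESETS)


def get_preset(name: str) -> MutantPreset:
    try:
        return _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; valid names: {', '.join(PRESET_NAMES)}"
        ) from None


def apply_preset(p: Params, preset: "MutantPreset | str") -> Params:
    """Return a new Params with the preset's overrides applied.

    The input Params is never mutated.  Scale overrides compose
    multiplicatively (applying a scale-k preset twice scales by k^2).
    """
    if isinstance(preset, str):
        preset = get_preset(preset)

    changes: dict[str, Any] = {}
    for fname, factor in preset.scales.items():
        current = getattr(p, fname)
        if isinstance(current, tuple):
            changes[fname] = tuple(
                x * factor if i < len(current) - 1 else x
                for i, x in enumerate(current)
            )
        else:
            changes[fname] = current * factor
    for fname, value in preset.sets.items():
        changes[fname] = value

    if preset.freeze_cyclase_dark:
        # freeze synthesis at this parameter set's dark-adapted rate so the
        # dark current is unchanged while all Ca2+ feedback is removed
        _, ca_dark = equilibria.dark_messengers(p)
        changes["alpha_freeze"] = cyclase_rate(ca_dark, p)

    return p.replace(**changes) if changes else p
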