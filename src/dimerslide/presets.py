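"""Access to the packaged parameter presets.

Presets live in ``data/presets.yaml`` and group the default model
parameters by stage: equilibrium binding, stoichiometry titrations,
activity (rate) titrations, simulator rate laws, and protomer species
attributes.  ``load_presets`` returns the raw mapping; the typed helpers
below construct the domain objects the rest of the package uses.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from typing import Any

import yaml

__all__ = [
    "load_presets",
    "binding_preset",
    "activity_preset",
    "stoichiometry_preset",
    "simulator_preset",
    "species_preset",
    "PresetError",
]


class PresetError(KeyError):
    """Unknown preset name."""


@lru_cache(maxsize=1)
def load_presets() -> dict[str, Any]:
    text = resources.files("dimerslide").joinpath("data/presets.yaml").read_text()
    return yaml.safe_load(text)


def _lookup(section: str, name: str) -> dict[str, Any]:
    table = load_presets().get(section, {})
    try:
        return dict(table[name])
    except KeyError:
        known = ", ".join(sorted(table))
        raise PresetError(
            f"unknown {section} preset {name!r}; available: {known}"
        ) from None


def binding_preset(name: str) -> dict[str, Any]:
    """Hill-model parameters for an equilibrium binding titration."""
    return _lookup("binding", name)


def activity_preset(name: str) -> dict[str, Any]:
    """Allosteric-sigmoidal parameters for a rate titration."""
    return _lookup("activity", name)


def stoichiometry_preset(name: str) -> dict[str, Any]:
    return _lookup("stoichiometry", name)


def simulator_preset(name: str) -> dict[str, Any]:
    return _lookup("simulator", name)


def species_preset(name: str) -> dict[str, Any]:
    return _lookup("species", name)
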