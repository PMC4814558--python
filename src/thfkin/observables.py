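"""Named steady-state observables shared by sensitivity, calibration and
the synthetic-data generator.

Observable grammar:

- ``conc:<species id>``   steady-state concentration
- ``flux:<reaction id>``  steady-state flux (signed)
- ``ratio:<sid>/<sid>``   concentration ratio
- ``total_folate``        [THF] + [CH2THF] (the only folate species here)
- ``pathway_flux``        flux through the FolA step, v_net + v_PanB
- ``drain_flux_total``    DRAIN_THF + DRAIN_CH2THF flux
"""

from __future__ import annotations

from typing import Callable

from .model import PathwayModel
from .simulate import SteadyState

__all__ = ["evaluate_observable", "resolve_observable"]


def evaluate_observable(name: str, model: PathwayModel, ss: SteadyState) -> float:
    return resolve_observable(name)(model, ss)


def resolve_observable(name: str) -> Callable[[PathwayModel, SteadyState], float]:
    if callable(name):
        return name
    if name == "total_folate":
        return lambda m, ss: ss.conc["THF"] + ss.conc["CH2THF"]
    if name == "pathway_flux":
        return lambda m, ss: ss.flux["FolA"]
    if name == "drain_flux_total":
        return lambda m, ss: ss.flux["DRAIN_THF"] + ss.flux["DRAIN_CH2THF"]
    if name.startswith("conc:"):
        sid = name[5:]
        return lambda m, ss: ss.conc[sid]
    if name.startswith("flux:"):
        rid = name[5:]
        return lambda m, ss: ss.flux[rid]
    if name.startswith("ratio:"):
        num, _, den = name[6:].partition("/")
        if not den:
            raise ValueError(f"ratio observable needs 'ratio:a/b', got {name!r}")
        return lambda m, ss: ss.conc[num] / ss.conc[den]
    raise ValueError(f"unknown observable {name!r}")
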