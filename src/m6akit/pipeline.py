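"""End-to-end driver: simulate (or load) libraries, assign, quantify, classify.

This is the convenience layer the examples and the acceptance script build
on; each stage remains individually callable from its own module.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .extent import extent_calls
from .models import FragmentLibrary, GenomeSequence, TranscriptModel
from .quantify import TranscriptAssignment, quantify
from .simulate import (
    SimulationParams,
    TruthTable,
    generate_reference,
    simulate_libraries,
)


@dataclass
class Experiment:
    genome: GenomeSequence
    models: list[TranscriptModel]
    truth: TruthTable | None
    params: SimulationParams | None
    libraries: dict[tuple[str, int, str], FragmentLibrary]
    assignments: dict[tuple[str, int, str], TranscriptAssignment] = field(
        default_factory=dict)
    quant: dict[tuple[str, int], pd.DataFrame] = field(default_factory=dict)

    @property
    def organs(self) -> list[str]:
        return list(dict.fromkeys(o for (o, _, _) in self.libraries))

    @property
    def replicates(self) -> list[int]:
        return sorted({r for (_, r, _) in self.libraries})

    def assignment(self, organ: str, rep: int, assay: str) -> TranscriptAssignment:
        key = (organ, rep, assay)
        if key not in self.assignments:
            self.assignments[key] = TranscriptAssignment(
                self.libraries[key], self.models)
        return self.assignments[key]

    def quantify(self, organ: str, rep: int) -> pd.DataFrame:
        key = (organ, rep)
        if key not in self.quant:
            self.quant[key] = quantify(
                self.assignment(organ, rep, "m6A"),
                self.assignment(organ, rep, "mRNA"),
                self.models,
            )
        return self.quant[key]

    def quant_all(self) -> pd.DataFrame:
        frames = [self.quantify(o, r) for o in self.organs
                  for r in self.replicates]
        return pd.concat(frames, ignore_index=True)

    def extent_calls(self, alpha: float = 0.05) -> pd.DataFrame:
        return extent_calls(self.quant_all(), alpha=alpha)


def run_simulation(params: SimulationParams,
                   assays: tuple[str, ...] = ("m6A", "mRNA")) -> Experiment:
    """Generate a reference and its libraries; input libraries are only
    simulated when requested (they are QC-only downstream)."""
    genome, models, truth = generate_reference(params)
    libs = simulate_libraries(genome, models, truth, params, assays=assays)
    lib_map = {(l.organ, l.replicate, l.assay): l for l in libs}
    return Experiment(genome=genome, models=models, truth=truth, params=params,
                      libraries=lib_map)
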