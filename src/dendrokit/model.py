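"""Model-folder assembly: morphology + biophys + channels -> runnable system.

The on-disk layout mirrors the modular format the rest of the package
reads and writes::

    model_dir/
      morphology/cell.swc
      biophys/biophys.json     three-section configuration
      biophys/mod/*.mod        channel mechanisms
      stimuli/*.json (+ .csv)  protocol parameters / element-wise locations

`CellModel` ties the pieces together and runs protocol dictionaries.
"""

from __future__ import annotations

import glob
import json
import os

import numpy as np

from . import channels as chmod
from .distributions import BiophysConfig, apply_config, read_config
from .morphology import Morphology, read_swc
from .simulator import (IClamp, Population, SimConfig, build_system,
                        integrate, place_population)


class CellModel:
    """A morphology with biophysics, ready to simulate."""

    def __init__(self, morph: Morphology, config: BiophysConfig,
                 channels: dict, d_lambda: float = 0.1):
        self.morph = morph
        self.config = config
        self.channels = channels
        if d_lambda is not None:
            morph.build_segments(d_lambda=d_lambda)
        self.params = apply_config(config, morph)

    @classmethod
    def from_folder(cls, path, d_lambda: float = 0.1) -> "CellModel":
        swc = glob.glob(os.path.join(path, "morphology", "*.swc"))
        if not swc:
            raise FileNotFoundError(f"no SWC file under {path}/morphology/")
        morph = read_swc(swc[0])
        config = read_config(os.path.join(path, "biophys", "biophys.json"))
        channels = {}
        for mod in sorted(glob.glob(os.path.join(path, "biophys", "mod", "*.mod"))):
            ch = chmod.parse_mod(mod)
            channels[ch.name] = ch
        return cls(morph, config, channels, d_lambda=d_lambda)

    # ------------------------------------------------------------- protocols

    def soma_segment(self):
        return self.morph.root_section.segments[0]

    def segments_of_domain(self, domain: str):
        return [s for s in self.morph.segments if s.domain == domain]

    def run(self, protocol: dict, seed: int = 0, recordings=None,
            extra_stimuli=(), v_init: float = -70.0):
        """Run one protocol dictionary and return Traces."""
        t_stop = protocol.get("t_stop", 300.0)
        cfg = SimConfig(t_stop=t_stop, v_init=v_init,
                        temperature=protocol.get("temperature", 37.0), seed=seed)
        stimuli = list(extra_stimuli)
        synapses = []
        if protocol.get("type") == "iclamp":
            if protocol.get("amplitude"):
                stimuli.append(IClamp(self.soma_segment(),
                                      protocol["amplitude"], protocol["delay"],
                                      protocol["duration"]))
        elif protocol.get("type") == "population":
            synapses = self._population_synapses(protocol, seed)
        if recordings is None:
            recordings = [self.soma_segment()]
        system = build_system(self.morph, self.params, self.channels,
                              synapses=synapses, stimuli=stimuli,
                              recordings=recordings, config=cfg)
        return integrate(system, cfg)

    def _population_synapses(self, protocol: dict, seed: int):
        rng = np.random.default_rng(seed)
        leaves = [s for s in self.morph.sections
                  if not s.children and s.domain != "soma"]
        if protocol.get("placement") == "clustered":
            k = min(protocol.get("n_branches") or 5, len(leaves))
            chosen = [leaves[i] for i in rng.choice(len(leaves), size=k, replace=False)]
        else:
            chosen = leaves
        targets = [seg for sec in chosen for seg in sec.segments]
        pop = Population(kind=protocol["kind"], n=protocol["n"], targets=targets,
                         rate=protocol["rate"], noise=protocol["noise"],
                         onset=protocol["onset"], duration=protocol["duration"])
        return place_population(pop, rng)


def load_protocol(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
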