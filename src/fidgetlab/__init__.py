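"""fidgetlab: fidget detection from behavioral video and analysis of
fidget-locked neural responses in mouse visual cortex.

The package covers the full chain: synthetic session generation with
ground truth (:mod:`~fidgetlab.synthdata`), HOG+PCA+SVM fidget detection
(:mod:`~fidgetlab.behavior`), optical-flow magnitude quantification
(:mod:`~fidgetlab.flow`), event-aligned response clustering and typing
(:mod:`~fidgetlab.neural`), anatomical decodability testing
(:mod:`~fidgetlab.decode`), behavioral-state modulation analysis
(:mod:`~fidgetlab.modulation`) and end-to-end orchestration
(:mod:`~fidgetlab.pipeline`).
"""

from . import behavior, flow, io, modulation, neural, synthdata

__all__ = ["behavior", "decode", "flow", "io", "modulation", "neural", "pipeline", "synthdata"]
__version__ = "0.1.0"


def __getattr__(name):
    # decode (umap/numba) and pipeline are imported lazily: importing umap
    # triggers numba compilation that most sessions never need
    if name in ("decode", "pipeline"):
        import importlib

        return importlib.import_module(f".{name}", __name__)
    raise AttributeError(name)
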