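"""follipulse: quantification toolkit for hair-follicle stem-cell mechanics.

Submodules
----------
volume    hair-germ volume normalization, behavior classification, contraction stats
afm       Hertz/Sneddon force-curve fits, force-map summaries, region comparisons
mechano   F-actin / nuclear-YAP scoring, permutation test, state classifier
actin     per-cell gene-set (actin) expression scores
recoil    laser-ablation recoil kinetics and tension-proxy comparisons
targets   miRNA seed-site scanning and duplex rendering
synth     seeded synthetic-data generators for all of the above
scenario  YAML-driven end-to-end simulate-and-analyze runner
io        CSV / MTX / FASTA readers and writers
"""

__version__ = "0.1.0"

from . import errors  # noqa: F401

__all__ = [
    "__version__",
    "errors",
    "volume",
    "afm",
    "mechano",
    "actin",
    "recoil",
    "targets",
    "synth",
    "scenario",
    "io",
    "stats",
]


def __getattr__(name):  # lazy submodule access keeps `import follipulse` light
    if name in __all__:
        import importlib

        return importlib.import_module(f".{name}", __name__)
    raise AttributeError(f"module 'follipulse' has no attribute {name!r}")
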