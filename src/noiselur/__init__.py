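"""noiselur: land-use-regression modelling of urban environmental noise.

The package covers the full chain of a noise LUR study at desk scale:
simulation of a synthetic city with a known acoustic ground truth,
equivalent-continuous-level and intermittency-ratio acoustics, buffer-based
spatial predictor extraction, mixed-effect model fitting with two-step
forward selection, site-grouped cross-validation, gridded prediction
surfaces, and enumeration-area population-exposure and socioeconomic
inequality summaries.
"""

__version__ = "0.1.0"

_SUBMODULES = (
    "acoustics",
    "evaluation",
    "exposure",
    "features",
    "geo",
    "lur",
    "mixedlm",
    "surfaces",
    "synthetic_city",
)


def __getattr__(name):
    if name in _SUBMODULES:
        import importlib

        return importlib.import_module(f".{name}", __name__)
    raise AttributeError(f"module {__name__!r} has no attribute {name!r}")


__all__ = list(_SUBMODULES) + ["__version__"]
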