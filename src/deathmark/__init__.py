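"""deathmark: two-arm prediction of suppressors of drug-induced cell death.

The package merges (i) per-gene Pearson correlations between drug-sensitivity
AUCs and cell-line expression / CRISPR essentiality with (ii) transcriptomic
similarity between drug-response signatures and public gene-knockdown
signatures, and aggregates both arms into ranked candidate-target lists.
"""

__version__ = "0.1.0"

from . import (  # noqa: F401
    config,
    diffexpr,
    dose_response,
    enrichment,
    predictors,
    ranking,
    signature_store,
    similarity,
    synthetic,
)

__all__ = [
    "__version__",
    "config",
    "diffexpr",
    "dose_response",
    "enrichment",
    "predictors",
    "ranking",
    "signature_store",
    "similarity",
    "synthetic",
    "pipeline",
]


def __getattr__(name):
    # pipeline imports back into the package; load lazily to avoid a cycle
    if name == "pipeline":
        from . import pipeline

        return pipeline
    raise AttributeError(f"module {__name__!r} has no attribute {name!r}")
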