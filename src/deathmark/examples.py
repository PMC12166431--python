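"""Access to the small worked-example tables shipped with the package:
a dose-response series for one breast-cancer line (MDA-MB-468), a
cell-line x inducer sensitivity-AUC table and a seven-gene predictor matrix."""

from importlib.resources import as_file, files
from pathlib import Path

__all__ = ["example_path"]

_NAMES = {
    "dose_response": "example_dose_response.csv",
    "auc": "example_auc.csv",
    "predictors": "example_predictors.csv",
}


def example_path(name: str) -> Path:
    """Filesystem path of a bundled example table: one of
    'dose_response', 'auc', 'predictors'."""
    if name not in _NAMES:
        raise KeyError(f"unknown example {name!r}; choose from {sorted(_NAMES)}")
    resource = files("deathmark") / "data" / _NAMES[name]
    with as_file(resource) as p:
        return Path(p)
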