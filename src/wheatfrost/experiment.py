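"""Field-experiment layout: varieties x nitrogen treatments x replicates.

The layout object models a winter-wheat nitrogen trial: each plot grows a
single variety under one urea-N rate, every (variety, treatment, replicate)
combination exists exactly once, and a fixed number of nadir photos is taken
per plot.  The default layout bundled with the package is a 128-variety,
3-treatment (0 / 180 / 240 kg ha^-1), 2-replicate design with 3 images per
plot — 768 plots and 2304 images in total.

Plot geometry (plot size, rows, row spacing) is carried as metadata only; no
downstream computation uses it.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

__all__ = [
    "NitrogenTreatment",
    "ExperimentLayout",
    "PlotID",
    "LayoutError",
    "enumerate_plots",
    "count_images",
    "load_layout",
    "default_layout",
]


class LayoutError(ValueError):
    """Raised when an experiment layout violates one of its invariants."""


@dataclass(frozen=True)
class NitrogenTreatment:
    """A nitrogen fertilization level.

    Parameters
    ----------
    label : str
        Short identifier, e.g. ``"N1"``.
    rate : float
        Urea-N application rate in kg ha^-1; must be non-negative.
    """

    label: str
    rate: float

    def __post_init__(self) -> None:
        if not self.label:
            raise LayoutError("treatment label must be a non-empty string")
        if self.rate < 0:
            raise LayoutError(
                f"treatment {self.label!r}: rate must be >= 0, got {self.rate}"
            )


@dataclass(frozen=True)
class PlotID:
    """Identifier of a single field plot within a layout."""

    variety: str
    treatment_label: str
    replicate: int

    def __str__(self) -> str:
        return f"{self.variety}_{self.treatment_label}_{self.replicate}"


@dataclass(frozen=True)
class ExperimentLayout:
    """Full factorial trial design.

    ``replicates`` counts whichever replicate axis multiplies plots (the
    bundled default uses 2); ``replicate_kind`` is free-text metadata.
    """

    varieties: tuple[str, ...]
    treatments: tuple[NitrogenTreatment, ...]
    replicates: int
    images_per_plot: int = 3
    plot_size_m: tuple[float, float] = (1.5, 1.5)
    rows_per_plot: int = 6
    row_spacing_cm: float = 25.0
    replicate_kind: str = "biological+technical"

    def __post_init__(self) -> None:
        object.__setattr__(self, "varieties", tuple(self.varieties))
        object.__setattr__(self, "treatments", tuple(self.treatments))
        self.validate()

    def validate(self) -> None:
        if len(self.varieties) < 1:
            raise LayoutError("layout needs at least one variety")
        if len(set(self.varieties)) != len(self.varieties):
            raise LayoutError("variety names must be unique")
        if len(self.treatments) < 1:
            raise LayoutError("layout needs at least one treatment")
        labels = [t.label for t in self.treatments]
        if len(set(labels)) != len(labels):
            raise LayoutError("treatment labels must be unique")
        if self.replicates < 1:
            raise LayoutError(f"replicates must be >= 1, got {self.replicates}")
        if self.images_per_plot < 1:
            raise LayoutError(
                f"images_per_plot must be >= 1, got {self.images_per_plot}"
            )
        if any(s <= 0 for s in self.plot_size_m):
            raise LayoutError("plot_size_m entries must be positive")
        if self.rows_per_plot < 1:
            raise LayoutError("rows_per_plot must be >= 1")
        if self.row_spacing_cm <= 0:
            raise LayoutError("row_spacing_cm must be positive")

    @property
    def n_plots(self) -> int:
        return len(self.varieties) * len(self.treatments) * self.replicates

    def treatment(self, label: str) -> NitrogenTreatment:
        for t in self.treatments:
            if t.label == label:
                return t
        raise KeyError(f"no treatment labelled {label!r} in layout")


def enumerate_plots(layout: ExperimentLayout) -> list[PlotID]:
    """All plot identifiers of a layout in deterministic order.

    Order is variety-major, then treatment (layout order), then replicate
    (1-based ascending), so batch outputs are reproducible.
    """
    layout.validate()
    return [
        PlotID(v, t.label, r)
        for v in layout.varieties
        for t in layout.treatments
        for r in range(1, layout.replicates + 1)
    ]


def count_images(layout: ExperimentLayout) -> int:
    """Total number of images the design calls for: plots x images per plot."""
    layout.validate()
    return layout.n_plots * layout.images_per_plot


def _autoname_varieties(n: int) -> tuple[str, ...]:
    width = max(3, len(str(n)))
    return tuple(f"V{i:0{width}d}" for i in range(1, n + 1))


def layout_from_dict(cfg: dict) -> ExperimentLayout:
    """Build a layout from a config mapping.

    ``varieties`` may be a list of names or an integer count (autonamed
    ``V001..Vnnn``).  ``treatments`` is a list of ``{label, rate}`` mappings.
    """
    varieties = cfg["varieties"]
    if isinstance(varieties, int):
        varieties = _autoname_varieties(varieties)
    treatments = tuple(
        NitrogenTreatment(label=str(t["label"]), rate=float(t["rate"]))
        for t in cfg["treatments"]
    )
    kwargs = {}
    for key in (
        "images_per_plot",
        "rows_per_plot",
        "row_spacing_cm",
        "replicate_kind",
    ):
        if key in cfg:
            kwargs[key] = cfg[key]
    if "plot_size_m" in cfg:
        kwargs["plot_size_m"] = tuple(cfg["plot_size_m"])
    return ExperimentLayout(
        varieties=tuple(varieties),
        treatments=treatments,
        replicates=int(cfg["replicates"]),
        **kwargs,
    )


def load_layout(path: str | Path) -> ExperimentLayout:
    """Read a layout from a YAML or JSON config file."""
    path = Path(path)
    text = path.read_text()
    cfg = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise LayoutError(f"layout config {path} did not parse to a mapping")
    return layout_from_dict(cfg)


def default_layout() -> ExperimentLayout:
    """The bundled default design: 128 varieties, N1/N2/N3, 2 replicates."""
    ref = importlib.resources.files("wheatfrost.data") / "default_layout.yaml"
    cfg = yaml.safe_load(ref.read_text())
    return layout_from_dict(cfg)
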