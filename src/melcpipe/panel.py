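"""Panel configuration: the ordered staining/imaging sequence of a MELC run.

A panel lists the numbered imaging steps (one marker each), which steps are
preceded by a negative-control (NC) acquisition of the bare secondary
antibody, and which marker pairs are treated as mutually exclusive for
background-level normalization.  A packaged 20-plex bone-marrow /
neuroblastoma panel is included as a worked fixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml


@dataclass
class PanelStep:
    """One numbered imaging step of the staining sequence."""

    index: int
    marker: str
    conjugate: str = ""
    is_negative_control: bool = False
    nc_partner: str | None = None  # name of the NC channel imaged before this step
    exclusive_partner: str | None = None  # mutually exclusive marker for normalization


@dataclass
class PanelConfig:
    steps: list[PanelStep]
    image_size_px: int = 2018
    pixel_size_um: float = 0.45
    nuclear_marker: str | None = None

    def __post_init__(self) -> None:
        indices = [s.index for s in self.steps]
        if indices != list(range(1, len(self.steps) + 1)):
            raise ValueError(f"step indices must be contiguous 1..N, got {indices}")
        names = {s.marker for s in self.steps}
        for s in self.steps:
            if s.exclusive_partner is not None and s.exclusive_partner not in names:
                raise ValueError(
                    f"exclusive partner {s.exclusive_partner!r} of {s.marker!r} "
                    "is not a panel marker"
                )
        if self.image_size_px <= 0 or self.pixel_size_um <= 0:
            raise ValueError("image size and pixel size must be positive")
        if self.nuclear_marker is not None and self.nuclear_marker not in names:
            raise ValueError(f"nuclear marker {self.nuclear_marker!r} not in panel")

    @property
    def markers(self) -> list[str]:
        return [s.marker for s in self.steps]

    @property
    def fov_size_um(self) -> float:
        """Physical side length of the field of view in micrometres."""
        return self.image_size_px * self.pixel_size_um

    @property
    def nc_pairs(self) -> dict[str, str]:
        return {s.marker: s.nc_partner for s in self.steps if s.nc_partner}

    @property
    def exclusive_pairs(self) -> dict[str, str]:
        return {s.marker: s.exclusive_partner for s in self.steps if s.exclusive_partner}

    def to_dict(self) -> dict:
        return {
            "image_size_px": self.image_size_px,
            "pixel_size_um": self.pixel_size_um,
            "nuclear_marker": self.nuclear_marker,
            "steps": [
                {
                    "index": s.index,
                    "marker": s.marker,
                    "conjugate": s.conjugate,
                    "is_negative_control": s.is_negative_control,
                    "nc_partner": s.nc_partner,
                    "exclusive_partner": s.exclusive_partner,
                }
                for s in self.steps
            ],
        }


def panel_from_dict(d: dict) -> PanelConfig:
    steps = [
        PanelStep(
            index=int(s["index"]),
            marker=str(s["marker"]),
            conjugate=str(s.get("conjugate", "")),
            is_negative_control=bool(s.get("is_negative_control", False)),
            nc_partner=s.get("nc_partner"),
            exclusive_partner=s.get("exclusive_partner"),
        )
        for s in d["steps"]
    ]
    return PanelConfig(
        steps=steps,
        image_size_px=int(d.get("image_size_px", 2018)),
        pixel_size_um=float(d.get("pixel_size_um", 0.45)),
        nuclear_marker=d.get("nuclear_marker"),
    )


def load_panel(path: str | Path) -> PanelConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if "panel" in d:
        d = d["panel"]
    return panel_from_dict(d)


def builtin_panel_path() -> Path:
    """Path of the packaged 20-plex bone-marrow panel fixture."""
    return Path(str(resources.files("melcpipe").joinpath("data/panel_20plex.yaml")))


def load_builtin_panel() -> PanelConfig:
    return load_panel(builtin_panel_path())
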