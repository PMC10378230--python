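"""Run configuration shared by the CLI and the report provenance block."""

from __future__ import annotations

from typing import Literal

from pydantic import BaseModel, ConfigDict, Field


class Tolerances(BaseModel):
    model_config = ConfigDict(extra="forbid")

    degenerate_mm: float = 1e-9
    angle_deg: float = 1e-6


class RunConfig(BaseModel):
    """Every method choice the analysis leaves open, with its default.

    Serialized verbatim into each report's provenance block so that any
    result can be re-derived from the report alone.
    """

    model_config = ConfigDict(extra="forbid")

    angle_convention: Literal["trace", "dihedral"] = "trace"
    mcfn_mode: Literal["tangent", "on_sphere"] = "tangent"
    delta_mm: float = Field(default=5.0, ge=0.1)
    neutral_angle_deg: float = 40.3
    frame: Literal["RAS", "LPS"] = "RAS"
    alpha: float = Field(default=0.05, gt=0, lt=1)
    seed: int = 0
    tolerances: Tolerances = Tolerances()
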