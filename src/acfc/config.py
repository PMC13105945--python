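"""Pipeline configuration: every tunable parameter of the ACFC analysis.

The defaults reproduce the squat-protocol analysis settings: 2-s/1-s
band-power windows for inter- and cardio-muscular coupling, 20-s/0.5-s
for respiratory-muscular coupling, 6-s/3-s windows for the dynamic
coupling time series, and the ten 19.5-Hz EMG bands with the 50-65 Hz
mains-notch exclusion.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import yaml

__all__ = ["PipelineConfig", "LINK_CLASS_PRESETS", "get_logger"]

log = logging.getLogger("acfc")


def get_logger(name: str = "acfc") -> logging.Logger:
    return logging.getLogger(name)


#: Named link-strength classification breakpoints.  The method itself leaves
#: the breakpoints to the analyst ("established according to the obtained
#: results"), so several documented presets are shipped: the generic methods
#: example and the inter-muscular / cardio / respiratory network examples.
LINK_CLASS_PRESETS: dict[str, tuple[float, ...]] = {
    "methods": (0.20, 0.35, 0.50, 0.65),
    "fig_intermuscular": (0.05, 0.15, 0.25, 0.35),
    "fig_cardio": (0.0, 0.10, 0.20, 0.30),
    "fig_resp": (0.15, 0.30, 0.45, 0.60),
}

LINK_CLASS_LABELS: tuple[str, ...] = ("weak", "intermediate", "strong", "very strong")


@dataclass
class PipelineConfig:
    """Resolved parameters for a full ACFC run.

    Window lengths are in seconds and must exceed their step.  ``hist_dc``
    is the coupling-histogram bin width Δc on the [-1, 1] axis.
    """

    # --- band scheme -------------------------------------------------
    band_low: float = 10.0
    band_width: float = 19.5
    band_count: int = 10
    bin_width: float = 0.5
    exclusions: tuple[tuple[float, float], ...] = ((50.0, 65.0),)
    spectrum_fmin: float = 10.0
    spectrum_fmax: float = 250.0
    taper: str = "hamming"

    # --- filtering ---------------------------------------------------
    emg_band: tuple[float, float] = (5.0, 250.0)
    ekg_band: tuple[float, float] = (0.5, 150.0)
    notch_center: float = 60.0
    notch_width: float = 1.0
    filter_order: int = 4

    # --- band-power windows ------------------------------------------
    bp_window: float = 2.0          # inter-/cardio-muscular analyses
    bp_step: float = 1.0
    resp_bp_window: float = 20.0    # respiratory-muscular analyses
    resp_bp_step: float = 0.5

    # --- rates --------------------------------------------------------
    hr_step: float = 1.0
    hr_artifact_window: float = 10.0
    hr_artifact_k: float = 2.0
    br_window: float = 20.0
    br_step: float = 0.5
    br_smooth: float = 2.0
    br_fmin: float = 0.05
    br_fmax: float = 1.0

    # --- coupling -----------------------------------------------------
    lag: float = 0.0
    dyn_window: float = 6.0
    dyn_step: float = 3.0
    link_classes: str = "methods"
    hist_dc: float = 0.05

    # --- DFA ----------------------------------------------------------
    dfa_order: int = 1
    dfa_n_scales: int = 15

    # --- misc ---------------------------------------------------------
    seed: int = 0

    def __post_init__(self) -> None:
        for win, step, name in (
            (self.bp_window, self.bp_step, "band-power"),
            (self.resp_bp_window, self.resp_bp_step, "respiratory band-power"),
            (self.br_window, self.br_step, "breathing-rate"),
            (self.dyn_window, self.dyn_step, "dynamic-coupling"),
        ):
            if not (win > step > 0):
                raise ValueError(f"{name} window must exceed its step and both must be > 0")
        if not (0 < self.hist_dc <= 2):
            raise ValueError("hist_dc must lie in (0, 2]")
        if self.link_classes not in LINK_CLASS_PRESETS:
            raise ValueError(
                f"unknown link-class preset {self.link_classes!r}; "
                f"choose from {sorted(LINK_CLASS_PRESETS)}"
            )

    # --- (de)serialisation -------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["exclusions"] = [list(z) for z in self.exclusions]
        d["emg_band"] = list(self.emg_band)
        d["ekg_band"] = list(self.ekg_band)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "exclusions" in d:
            d["exclusions"] = tuple(tuple(z) for z in d["exclusions"])
        for key in ("emg_band", "ekg_band"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def log_resolved(self, stage: str) -> None:
        """Log the effective parameters so runs are auditable."""
        log.info("stage=%s resolved-config=%s", stage, self.to_dict())
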