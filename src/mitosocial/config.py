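"""Shared analysis configuration.

Defaults follow the published imaging/analysis protocol for Arabidopsis
hypocotyl cells: mitochondrial encounters are close approaches within
1.6 µm (just over one mitochondrion's length), chloroplast adjacency is
within d = 3 µm of a chloroplast centre (twice the typical 1.5 µm
chloroplast radius), images are calibrated at 5 pixels per µm, trajectory
gap closing spans at most 2 missed frames, and each cell is summarised
over a 233 s observation window.
"""

from __future__ import annotations

from dataclasses import dataclass, field


#: Encounter / co-localization distance threshold in µm.
DEFAULT_ENCOUNTER_THRESHOLD_UM = 1.6

#: Chloroplast-adjacency distance d in µm (2 × typical 1.5 µm radius).
DEFAULT_CHLORO_ADJACENCY_UM = 3.0

#: Typical chloroplast radius in µm.
CHLOROPLAST_RADIUS_UM = 1.5

#: Image calibration, pixels per µm.
DEFAULT_PIXEL_SCALE = 5.0

#: Maximum frame gap closed by the upstream tracker.
DEFAULT_MAX_FRAME_GAP = 2

#: Length of the analysis window in seconds.
DEFAULT_WINDOW_S = 233.0


@dataclass
class AnalysisConfig:
    """Tunable parameters of the trajectory analysis.

    Attributes
    ----------
    encounter_threshold_um
        Distance (µm) at or below which two mitochondria in the same frame
        count as encountering each other.
    chloro_adjacency_um
        Distance d (µm) from a chloroplast centre within which a
        mitochondrion counts as chloroplast-adjacent.
    pixel_scale
        Pixels per µm used when converting pixel-unit exports.
    max_frame_gap
        Largest within-track frame gap accepted by validation.
    window_s
        Observation-window length in seconds used for the full-window
        summaries.
    checkpoint_fractions
        Fractions of the full window at which the time-resolved network
        series is evaluated (quarter/half/three-quarter/full by default).
    """

    encounter_threshold_um: float = DEFAULT_ENCOUNTER_THRESHOLD_UM
    chloro_adjacency_um: float = DEFAULT_CHLORO_ADJACENCY_UM
    pixel_scale: float = DEFAULT_PIXEL_SCALE
    max_frame_gap: int = DEFAULT_MAX_FRAME_GAP
    window_s: float = DEFAULT_WINDOW_S
    checkpoint_fractions: tuple[float, ...] = (0.25, 0.5, 0.75, 1.0)

    def checkpoints(self, n_frames: int) -> list[int]:
        """Frame indices (inclusive window ends) for the network series."""
        pts = sorted({max(0, int(round(f * (n_frames - 1)))) for f in self.checkpoint_fractions})
        return pts
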