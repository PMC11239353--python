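"""Region-of-interest table and the movie event-window schedule.

The default ROI set is the 12-region Theory-of-Mind / pain parcellation used
for the "Partly Cloudy" movie paradigm: six ToM-network regions (bilateral
TPJ, PCC, vmPFC, dmPFC, precuneus) and six pain-network regions (bilateral
MFG, anterior insula, secondary sensory cortex), each defined by a spherical
mask at an MNI peak. MNI coordinates are carried as metadata only; no
computation in this package uses them.

The default window schedule covers the ten high-activation movie events
(five ToM scenes T1-T5, five pain scenes P1-P5) at TR = 2 s, 168 time points
in total. The per-event lengths are not individually published, so the
schedule splits the 168 points evenly: 17,17,17,17,16 per network.
"""

from __future__ import annotations

from dataclasses import dataclass, field


TOM = "ToM"
PAIN = "Pain"


@dataclass(frozen=True)
class RoiSet:
    """An ordered set of named ROIs with network tags and MNI coordinates."""

    names: tuple[str, ...]
    networks: tuple[str, ...]
    mni: tuple[tuple[int, int, int], ...]

    def __post_init__(self):
        if len(set(self.names)) != len(self.names):
            raise ValueError("ROI names must be unique")
        if not (len(self.names) == len(self.networks) == len(self.mni)):
            raise ValueError("names, networks and mni must have equal length")
        bad = [n for n in self.networks if n not in (TOM, PAIN)]
        if bad:
            raise ValueError(f"unknown network tag(s): {bad}")

    def __len__(self) -> int:
        return len(self.names)

    def indices(self, network: str) -> list[int]:
        return [i for i, n in enumerate(self.networks) if n == network]

    def subset(self, names: list[str] | tuple[str, ...]) -> "RoiSet":
        idx = [self.names.index(n) for n in names]
        return RoiSet(
            names=tuple(self.names[i] for i in idx),
            networks=tuple(self.networks[i] for i in idx),
            mni=tuple(self.mni[i] for i in idx),
        )


_DEFAULT_ROIS = [
    # (name, network, (x, y, z))
    ("PCC", TOM, (0, -52, 18)),
    ("LTPJ", TOM, (-46, -68, 32)),
    ("RTPJ", TOM, (46, -68, 32)),
    ("vmPFC", TOM, (4, 48, -4)),
    ("Precuneus", TOM, (0, -49, 40)),
    ("dmPFC", TOM, (-10, 58, 24)),
    ("RMFG", PAIN, (36, 38, 40)),
    ("LMFG", PAIN, (-36, 38, 40)),
    ("LII", PAIN, (-40, 22, 0)),
    ("RII", PAIN, (39, 23, -4)),
    ("LSSC", PAIN, (-39, -15, 18)),
    ("RSSC", PAIN, (39, -15, 18)),
]


def default_rois() -> RoiSet:
    """The 12-ROI ToM + pain set (6 ToM, 6 pain) with MNI peak coordinates."""
    return RoiSet(
        names=tuple(r[0] for r in _DEFAULT_ROIS),
        networks=tuple(r[1] for r in _DEFAULT_ROIS),
        mni=tuple(r[2] for r in _DEFAULT_ROIS),
    )


@dataclass(frozen=True)
class EventWindow:
    """One high-activation movie event: a contiguous run of TRs with a state label."""

    label: str  # ToM or Pain
    start_tp: int
    end_tp: int  # exclusive
    description: str = ""

    def __post_init__(self):
        if self.label not in (TOM, PAIN):
            raise ValueError(f"window label must be {TOM!r} or {PAIN!r}")
        if self.end_tp <= self.start_tp:
            raise ValueError("end_tp must exceed start_tp")
        if self.length < 5:
            raise ValueError("windows must span at least 5 time points (>8 s at TR 2 s)")

    @property
    def length(self) -> int:
        return self.end_tp - self.start_tp

    @property
    def name(self) -> str:
        return self.description.split(":", 1)[0] if self.description else self.label


_TOM_EVENTS = [
    "T1: Peck flies away to happy cloud",
    "T2: Peck caught gazing at happy clouds",
    "T3: Baby crying, then happy",
    "T4: Peck dons gear to show why he left",
    "T5: Pan from happy clouds to lonely cloud (Gus)",
]
_PAIN_EVENTS = [
    "P1: Gus pulls porcupine spines from Peck's head",
    "P2: Alligator biting Peck",
    "P3: Peck tossing porcupine",
    "P4: Cloud makes animals (lightning)",
    "P5: Gus makes alligator (lightning)",
]
_LENGTHS = [17, 17, 17, 17, 16]


def default_windows() -> list[EventWindow]:
    """Ten interleaved ToM/Pain event windows tiling 168 time points."""
    windows = []
    t = 0
    for i in range(5):
        for label, desc in ((TOM, _TOM_EVENTS[i]), (PAIN, _PAIN_EVENTS[i])):
            windows.append(EventWindow(label, t, t + _LENGTHS[i], desc))
            t += _LENGTHS[i]
    return windows
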