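"""Synthetic SimBaby-style breathing protocols and RFID interrogation streams.

No public recording of the mannequin protocol exists, so this module generates
one: a ground-truth breathing/apnea timeline (breathing at 31 breaths/min,
apnea pauses of 30/45/60 s alternating over an hour) and the RFID backscatter
stream a UHF interrogator would observe while polling a chest-worn passive tag
through 50 hopping channels in the 902-928 MHz band.

The forward model is the radar cross-section link budget

    P_Rx = P_Tx * G_reader^2 * G_tag^2 * R * (lambda / (4 pi r))^4

with chest-wall motion during breathing modulating the tag gain ``G_tag`` and
return loss ``R`` sinusoidally at the breath rate. During apnea the modulation
amplitude is zero, so received power varies only with the hop channel and
measurement noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from neorespire.errors import ParseError, ValidationError

SPEED_OF_LIGHT_M_S = 299_792_458.0

CSV_HEADER = ("timestamp_s", "channel_mhz", "rssi_dbm")


# ---------------------------------------------------------------------------
# Protocol and timeline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BreathingProtocol:
    """Mannequin programming: breath rate and the alternating segment plan.

    The default plan repeats [120 s breathing, 30 s apnea, 120 s breathing,
    45 s apnea, 120 s breathing, 60 s apnea] until ``total_duration`` is
    tiled; the final segment is truncated to fit exactly.
    """

    breaths_per_minute: float = 31.0
    apnea_durations: Sequence[float] = (30.0, 45.0, 60.0)
    breathing_segment_durations: Sequence[float] = (120.0, 120.0, 120.0)
    total_duration: float = 3600.0

    def __post_init__(self):
        if self.breaths_per_minute <= 0:
            raise ValidationError("breaths_per_minute must be positive")
        if self.total_duration <= 0:
            raise ValidationError("total_duration must be positive")
        for d in tuple(self.apnea_durations) + tuple(self.breathing_segment_durations):
            if d <= 0:
                raise ValidationError(f"segment durations must be positive, got {d}")
        if not self.apnea_durations and not self.breathing_segment_durations:
            raise ValidationError("at least one segment duration is required")


@dataclass(frozen=True)
class Segment:
    start_s: float
    end_s: float
    state: int  # 1 breathing, 0 apnea

    @property
    def duration(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class GroundTruthTimeline:
    """Contiguous, alternating breathing/apnea segments tiling [0, duration].

    During breathing segments the chest displacement follows a sinusoid at
    ``breaths_per_minute``; each breathing segment starts at phase zero.
    """

    segments: tuple[Segment, ...]
    breaths_per_minute: float

    def __post_init__(self):
        if not self.segments:
            raise ValidationError("timeline needs at least one segment")
        prev = None
        for seg in self.segments:
            if seg.end_s <= seg.start_s:
                raise ValidationError("segments must have positive duration")
            if prev is not None:
                if not math.isclose(prev.end_s, seg.start_s, abs_tol=1e-9):
                    raise ValidationError("segments must be contiguous")
                if prev.state == seg.state:
                    raise ValidationError("segment states must alternate")
            prev = seg

    @property
    def duration(self) -> float:
        return self.segments[-1].end_s

    def state_at(self, t: np.ndarray | float) -> np.ndarray:
        """Breathing state (1/0) at time(s) t; half-open segments [start, end)."""
        t = np.asarray(t, dtype=float)
        starts = np.array([s.start_s for s in self.segments])
        states = np.array([s.state for s in self.segments], dtype=int)
        idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, len(starts) - 1)
        return states[idx]

    def modulation_phase(self, t: np.ndarray | float) -> np.ndarray:
        """sin(2 pi f_b (t - segment start)) during breathing, 0 during apnea."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        f_b = self.breaths_per_minute / 60.0
        for seg in self.segments:
            if seg.state != 1:
                continue
            m = (t >= seg.start_s) & (t < seg.end_s)
            out[m] = np.sin(2.0 * np.pi * f_b * (t[m] - seg.start_s))
        return out

    def to_dict(self) -> dict:
        return {
            "breaths_per_minute": self.breaths_per_minute,
            "segments": [[s.start_s, s.end_s, s.state] for s in self.segments],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruthTimeline":
        segs = tuple(Segment(a, b, int(s)) for a, b, s in d["segments"])
        return cls(segments=segs, breaths_per_minute=float(d["breaths_per_minute"]))


def generate_protocol(protocol: BreathingProtocol, seed: int | None = None) -> GroundTruthTimeline:
    """Expand a protocol into a ground-truth timeline tiling [0, total_duration].

    The plan is deterministic (alternating segments in the order listed,
    repeated cyclically, final segment truncated); ``seed`` is accepted for
    interface symmetry with the stochastic generators and reserved for
    randomized segment plans.
    """
    breathing = tuple(protocol.breathing_segment_durations)
    apnea = tuple(protocol.apnea_durations)

    def plan() -> Iterator[tuple[float, int]]:
        i = 0
        while True:
            if breathing:
                yield breathing[i % len(breathing)], 1
            if apnea:
                yield apnea[i % len(apnea)], 0
            i += 1

    segments: list[Segment] = []
    t = 0.0
    total = protocol.total_duration
    for dur, state in plan():
        if t >= total - 1e-12:
            break
        end = min(t + dur, total)
        if segments and segments[-1].state == state:
            # only happens when one of the lists is empty: merge
            segments[-1] = Segment(segments[-1].start_s, end, state)
        else:
            segments.append(Segment(t, end, state))
        t = end
    return GroundTruthTimeline(segments=tuple(segments), breaths_per_minute=protocol.breaths_per_minute)


# ---------------------------------------------------------------------------
# RFID forward model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RFIDConfig:
    """Interrogator/tag geometry, channel plan, and noise model.

    The aggregate poll rate is ~90 Hz but collisions leave an effective
    ~28 Hz per tag; only the net per-tag rate is simulated. ``modulation_depth``
    is the fractional sinusoidal perturbation of tag gain and return loss
    caused by chest motion; ``noise_sd_db`` is additive Gaussian noise on the
    reported RSSI in dB.
    """

    interrogation_rate_total: float = 90.0
    effective_rate_per_tag: float = 28.0
    n_channels: int = 50
    band_mhz: tuple[float, float] = (902.0, 928.0)
    p_tx_w: float = 1.0
    g_reader: float = 3.98       # ~6 dBi
    g_tag: float = 1.26          # ~1 dBi knitted antenna
    return_loss: float = 0.5
    nominal_r_m: float = 0.3048  # 1 ft interrogator-tag distance
    noise_sd_db: float = 0.1
    modulation_depth: float = 0.05
    arrival: str = "jittered"    # 'jittered' uniform or 'poisson'

    def __post_init__(self):
        if self.effective_rate_per_tag > self.interrogation_rate_total:
            raise ValidationError("effective_rate_per_tag must be <= interrogation_rate_total")
        if self.effective_rate_per_tag <= 0:
            raise ValidationError("effective_rate_per_tag must be positive")
        if self.n_channels < 1:
            raise ValidationError("n_channels must be >= 1")
        if self.p_tx_w <= 0:
            raise ValidationError("P_Tx must be positive")
        if not (0 <= self.modulation_depth < 1):
            raise ValidationError("modulation_depth must be in [0, 1)")
        if self.noise_sd_db < 0:
            raise ValidationError("noise_sd_db must be >= 0")
        if self.band_mhz[1] <= self.band_mhz[0]:
            raise ValidationError("band upper edge must exceed lower edge")
        if self.arrival not in ("jittered", "poisson"):
            raise ValidationError("arrival must be 'jittered' or 'poisson'")

    def channel_frequencies_mhz(self) -> np.ndarray:
        """Equally spaced channel centers inside the band."""
        lo, hi = self.band_mhz
        spacing = (hi - lo) / self.n_channels
        return lo + spacing * (np.arange(self.n_channels) + 0.5)


@dataclass(frozen=True)
class InterrogationRecord:
    """One RFID poll: when, on which channel, at what received power."""

    timestamp_s: float
    channel_mhz: float
    rssi_dbm: float


class InterrogationStream:
    """Column-oriented container for a time-sorted interrogation stream.

    Iterating yields :class:`InterrogationRecord`; bulk consumers read the
    ``timestamp_s`` / ``channel_mhz`` / ``rssi_dbm`` arrays directly.
    """

    def __init__(self, timestamp_s, channel_mhz, rssi_dbm, band_mhz: tuple[float, float] | None = None):
        self.timestamp_s = np.asarray(timestamp_s, dtype=float)
        self.channel_mhz = np.asarray(channel_mhz, dtype=float)
        self.rssi_dbm = np.asarray(rssi_dbm, dtype=float)
        n = len(self.timestamp_s)
        if len(self.channel_mhz) != n or len(self.rssi_dbm) != n:
            raise ValidationError("stream columns must have equal length")
        if n > 1 and not np.all(np.diff(self.timestamp_s) > 0):
            raise ValidationError("timestamps must be strictly increasing")
        if band_mhz is not None and n > 0:
            lo, hi = band_mhz
            if self.channel_mhz.min() < lo or self.channel_mhz.max() > hi:
                raise ValidationError("channel frequency outside band")

    def __len__(self) -> int:
        return len(self.timestamp_s)

    def __iter__(self) -> Iterator[InterrogationRecord]:
        for t, f, p in zip(self.timestamp_s, self.channel_mhz, self.rssi_dbm):
            yield InterrogationRecord(float(t), float(f), float(p))

    def __eq__(self, other) -> bool:
        if not isinstance(other, InterrogationStream):
            return NotImplemented
        return (
            np.array_equal(self.timestamp_s, other.timestamp_s)
            and np.array_equal(self.channel_mhz, other.channel_mhz)
            and np.array_equal(self.rssi_dbm, other.rssi_dbm)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestamp_s": self.timestamp_s,
                "channel_mhz": self.channel_mhz,
                "rssi_dbm": self.rssi_dbm,
            }
        )


def _arrival_times(duration: float, rate: float, mode: str, rng: np.random.Generator) -> np.ndarray:
    if mode == "poisson":
        # exponential gaps; expected count rate*duration
        n_guess = int(rate * duration * 1.5) + 20
        gaps = rng.exponential(1.0 / rate, size=n_guess)
        t = np.cumsum(gaps)
        while t[-1] < duration:
            gaps = rng.exponential(1.0 / rate, size=n_guess)
            t = np.concatenate([t, t[-1] + np.cumsum(gaps)])
        return t[t < duration]
    # jittered-uniform: one poll per 1/rate slot, jittered within 90% of the
    # slot so ordering stays strict
    n = int(math.floor(rate * duration))
    u = rng.random(n)
    return (np.arange(n) + 0.9 * u) / rate


def simulate_interrogations(
    timeline: GroundTruthTimeline, cfg: RFIDConfig = RFIDConfig(), seed: int = 0
) -> InterrogationStream:
    """Simulate the backscatter stream an interrogator observes.

    Polls arrive at ``cfg.effective_rate_per_tag``; channels advance
    round-robin one hop per poll. Received power follows the RCS link budget
    with breathing modulating tag gain and return loss by
    ``(1 + m sin(2 pi f_b t))``; the dBm reading gets additive Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    t = _arrival_times(timeline.duration, cfg.effective_rate_per_tag, cfg.arrival, rng)
    n = len(t)
    channels = cfg.channel_frequencies_mhz()
    f_mhz = channels[np.arange(n) % cfg.n_channels]
    lam = SPEED_OF_LIGHT_M_S / (f_mhz * 1e6)

    mod = cfg.modulation_depth * timeline.modulation_phase(t)
    g_tag = cfg.g_tag * (1.0 + mod)
    r_loss = cfg.return_loss * (1.0 + mod)
    p_rx_w = (
        cfg.p_tx_w
        * cfg.g_reader**2
        * g_tag**2
        * r_loss
        * (lam / (4.0 * np.pi * cfg.nominal_r_m)) ** 4
    )
    rssi_dbm = 10.0 * np.log10(p_rx_w / 1e-3)
    if cfg.noise_sd_db > 0:
        rssi_dbm = rssi_dbm + rng.normal(0.0, cfg.noise_sd_db, size=n)
    return InterrogationStream(t, f_mhz, rssi_dbm, band_mhz=cfg.band_mhz)


# ---------------------------------------------------------------------------
# CSV plumbing
# ---------------------------------------------------------------------------

def write_interrogations_csv(stream: InterrogationStream, path) -> None:
    """Write `timestamp_s,channel_mhz,rssi_dbm` rows; shortest-repr floats
    give exact round-trips."""
    stream.to_frame().to_csv(path, index=False)


def read_interrogations_csv(path) -> InterrogationStream:
    """Read a stream back; malformed numeric cells raise ParseError naming
    the 1-based file line."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CSV_HEADER if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    cols = {}
    for c in CSV_HEADER:
        probe = pd.to_numeric(df[c], errors="coerce")  # lossy, for validation only
        bad = np.flatnonzero(probe.isna().to_numpy())
        if bad.size:
            line = int(bad[0]) + 2  # +1 header, +1 1-based
            raise ParseError(f"{path}: non-numeric value {df[c].iloc[bad[0]]!r} in column '{c}' at line {line}")
        # numpy's str->float conversion is correctly rounded (round-trip exact)
        cols[c] = df[c].to_numpy().astype(np.float64)
    return InterrogationStream(cols["timestamp_s"], cols["channel_mhz"], cols["rssi_dbm"])
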