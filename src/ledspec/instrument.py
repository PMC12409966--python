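"""Virtual six-channel LED spectrophotometer.

Models the observable behaviour of the instrument: six cuvette positions,
each with its own LED (a Gaussian emission band), a light-to-frequency
sensor that outputs a square wave whose frequency is proportional to the
transmitted intensity (linear up to 500 kHz), per-channel blank zeroing, and
the firmware's absorbance computation

    A = log10(f_r / f)

where ``f_r`` is the reference frequency recorded on a blank and ``f`` the
current frequency.  The three-button front panel (zero, cuvette increment,
cuvette decrement, and their combinations) and the two-line LCD are emulated
so that scripted interaction matches what a user of the physical instrument
would see.

Measurement noise is multiplicative Gaussian on the frequency with relative
standard deviation ``ln(10) * noise_sd_abs``, which makes repeated absorbance
readings fluctuate with standard deviation ``noise_sd_abs`` (default 1e-3,
i.e. in the third decimal place).  All randomness comes from a per-instrument
seeded generator, so identical seeds give bit-identical read sequences.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import yaml

from .optics import Sample, transmitted_intensity
from .spectra import GaussianPeak, Spectrum, gaussian_emission

__all__ = [
    "LINEAR_CEILING_HZ",
    "SensorModel",
    "LedChannelConfig",
    "ChannelState",
    "InstrumentState",
    "led_current",
    "load_instrument_config",
]

#: Frequency ceiling of the light-to-frequency sensor's linear range (Hz).
LINEAR_CEILING_HZ = 500_000

#: Default LED forward voltage drop (V); typical for 5 mm visible LEDs and
#: chosen so a 330 ohm dropping resistor at 5 V passes 10 mA.
DEFAULT_FORWARD_VOLTAGE = 1.7

DEFAULT_NOISE_SD_ABS = 1.0e-3


@dataclass
class SensorModel:
    """Light-to-frequency converter: output frequency = responsivity x intensity."""

    responsivity: float  # Hz per relative-intensity unit
    linear_ceiling: int = LINEAR_CEILING_HZ
    noise_sd_abs: float = DEFAULT_NOISE_SD_ABS  # absorbance-equivalent noise sd

    def __post_init__(self) -> None:
        if not self.responsivity > 0:
            raise ValueError("responsivity must be positive")
        if self.linear_ceiling != LINEAR_CEILING_HZ:
            raise ValueError("sensor linear ceiling is fixed at 500,000 Hz")


@dataclass
class LedChannelConfig:
    """Electrical and spectral configuration of one LED channel."""

    emission: GaussianPeak
    dropping_resistor: float  # ohm
    forward_voltage: float = DEFAULT_FORWARD_VOLTAGE  # V
    supply_voltage: float = 5.0  # V

    def __post_init__(self) -> None:
        if not self.dropping_resistor > 0:
            raise ValueError("dropping_resistor must be positive")
        if self.forward_voltage >= self.supply_voltage:
            raise ValueError(
                "forward voltage must be below the supply voltage (LED cannot conduct)"
            )


def led_current(config: LedChannelConfig) -> float:
    """LED drive current in amperes: (V_supply - V_forward) / R_drop."""
    return (config.supply_voltage - config.forward_voltage) / config.dropping_resistor


@dataclass
class ChannelState:
    """One cuvette position: LED, sensor, sample, stored reference frequency."""

    position: int  # 1-6
    config: LedChannelConfig
    sensor: SensorModel
    sample: Optional[Sample] = None  # None = blank cuvette
    reference_frequency: Optional[float] = None  # f_r, Hz

    def __post_init__(self) -> None:
        if self.position not in range(1, 7):
            raise ValueError("position must be in 1..6")
        if self.reference_frequency is not None and not self.reference_frequency > 0:
            raise ValueError("reference frequency must be positive when set")
        self._source_cache: Optional[Spectrum] = None

    @property
    def source(self) -> Spectrum:
        """LED emission spectrum for this channel (cached)."""
        if self._source_cache is None:
            self._source_cache = gaussian_emission(self.config.emission)
        return self._source_cache


@dataclass
class LogEvent:
    timestamp: float
    kind: str  # zero / read / press / command
    position: int
    value: object = None

    def format(self) -> str:
        return f"{self.timestamp:.3f}\t{self.kind}\tpos={self.position}\t{self.value}"


class InstrumentState:
    """Mutable state of a powered virtual spectrophotometer.

    Exactly six channels, one active position at a time (the multiplexer is
    modelled only as that constraint).  All mutating operations return
    ``self`` so calls can be chained.
    """

    def __init__(
        self,
        channels: Iterable[ChannelState],
        rng_seed: int = 0,
        beep_enabled: bool = True,
    ) -> None:
        channels = list(channels)
        if len(channels) != 6 or sorted(c.position for c in channels) != [1, 2, 3, 4, 5, 6]:
            raise ValueError("an instrument has exactly six channels, positions 1..6")
        self.channels = {c.position: c for c in channels}
        self.active_position = 1
        self.beep_enabled = beep_enabled
        self.intensity_mode = False  # display raw frequency instead of absorbance
        self.rng_seed = rng_seed
        self.rng = np.random.default_rng(rng_seed)
        self.log: list[LogEvent] = []

    # -- internals ---------------------------------------------------------

    def _log(self, kind: str, position: int, value=None) -> None:
        self.log.append(LogEvent(time.time(), kind, position, value))

    def channel(self, position: int) -> ChannelState:
        if position not in self.channels:
            raise ValueError("position must be in 1..6")
        return self.channels[position]

    # -- measurement path --------------------------------------------------

    def measure_frequency(self, position: int | None = None) -> tuple[int, bool]:
        """One sensor reading at a position: (frequency in Hz, saturated flag).

        The frequency is responsivity x band-integrated transmitted intensity,
        perturbed by multiplicative Gaussian noise, counted over a 1 s gate and
        therefore rounded to an integer.  Readings above the 500 kHz linear
        ceiling are flagged as saturated but NOT clamped: the firmware shows
        them so the user knows to fit a larger dropping resistor.
        """
        pos = self.active_position if position is None else position
        ch = self.channel(pos)
        sample = ch.sample
        if sample is None:
            intensity = ch.source.integral()  # blank: nothing absorbed
        else:
            intensity = transmitted_intensity(ch.source, sample)
        freq = ch.sensor.responsivity * intensity
        if ch.sensor.noise_sd_abs > 0:
            rel_sd = np.log(10.0) * ch.sensor.noise_sd_abs
            freq *= 1.0 + rel_sd * self.rng.standard_normal()
        freq_hz = int(round(max(freq, 0.0)))
        saturated = freq_hz > ch.sensor.linear_ceiling
        return freq_hz, saturated

    def zero(self, position: int | None = None) -> "InstrumentState":
        """Record the current frequency as the blank reference f_r."""
        pos = self.active_position if position is None else position
        freq, _ = self.measure_frequency(pos)
        if freq == 0:
            raise ValueError(f"cannot zero position {pos}: measured frequency is 0 (dark channel)")
        self.channel(pos).reference_frequency = float(freq)
        self._log("zero", pos, freq)
        return self

    def zero_all(self) -> "InstrumentState":
        """Step through all six positions and zero each."""
        for pos in range(1, 7):
            self.zero(pos)
        return self

    def power_on(self) -> "InstrumentState":
        """Warm-up sequence: zero all positions, return to position 1."""
        self.zero_all()
        self.active_position = 1
        return self

    def read_absorbance(self, position: int | None = None) -> float:
        """Absorbance at a position: A = log10(f_r / f)."""
        pos = self.active_position if position is None else position
        ch = self.channel(pos)
        if ch.reference_frequency is None:
            raise ValueError(f"position {pos} has no reference frequency; zero it first")
        freq, _ = self.measure_frequency(pos)
        if freq == 0:
            raise ValueError(f"position {pos} reads frequency 0; cannot form log ratio")
        a = float(np.log10(ch.reference_frequency / freq))
        self._log("read", pos, a)
        return a

    # -- front panel -------------------------------------------------------

    def insert_sample(self, position: int, sample: Optional[Sample]) -> "InstrumentState":
        """Place a sample (or None for a blank) in a cuvette position."""
        self.channel(position).sample = sample
        return self

    def press(self, buttons: set[str] | frozenset[str]) -> tuple["InstrumentState", tuple[str, str]]:
        """Apply a front-panel button press (a non-empty subset of
        {"zero", "inc", "dec"}) and return (state, display lines)."""
        buttons = frozenset(buttons)
        if not buttons or not buttons <= {"zero", "inc", "dec"}:
            raise ValueError("buttons must be a non-empty subset of {'zero', 'inc', 'dec'}")
        old_pos = self.active_position
        if buttons == {"inc", "dec"}:
            self.active_position = 1
        elif buttons == {"inc"}:
            self.active_position = 1 if self.active_position == 6 else self.active_position + 1
        elif buttons == {"dec"}:
            self.active_position = 6 if self.active_position == 1 else self.active_position - 1
        elif buttons == {"zero"}:
            self.zero()
        elif buttons == {"zero", "dec"}:
            self.zero_all()
        elif buttons == {"zero", "inc"}:
            self.intensity_mode = not self.intensity_mode
        beeped = self.beep_enabled and self.active_position != old_pos
        self._log("press", self.active_position, {"buttons": sorted(buttons), "beep": beeped})
        return self, self.render_display()

    def render_display(self) -> tuple[str, str]:
        """The two LCD lines: absorbance (3 decimals) or raw frequency, and
        the active cuvette position."""
        if self.intensity_mode:
            freq, _ = self.measure_frequency()
            line1 = f"Freq: {freq}"
        else:
            line1 = f"Abs: {self.read_absorbance():.3f}"
        return line1, f"Cuvette {self.active_position}"

    def format_log(self) -> str:
        return "\n".join(ev.format() for ev in self.log)


def load_instrument_config(path) -> InstrumentState:
    """Build an instrument from a key-value (YAML) configuration file.

    Expected layout::

        seed: 1
        beep: true
        noise_sd_abs: 0.001
        channels:
          - {peak_nm: 405, fwhm_nm: 15, resistor_ohm: 660,
             forward_voltage_v: 1.7, responsivity_hz: 12000}
          # ... one entry per position, six total
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    noise = float(cfg.get("noise_sd_abs", DEFAULT_NOISE_SD_ABS))
    channels = []
    for i, ch in enumerate(cfg["channels"], start=1):
        emission = GaussianPeak(float(ch["peak_nm"]), float(ch["fwhm_nm"]))
        config = LedChannelConfig(
            emission=emission,
            dropping_resistor=float(ch["resistor_ohm"]),
            forward_voltage=float(ch.get("forward_voltage_v", DEFAULT_FORWARD_VOLTAGE)),
        )
        sensor = SensorModel(responsivity=float(ch["responsivity_hz"]), noise_sd_abs=noise)
        channels.append(ChannelState(position=i, config=config, sensor=sensor))
    return InstrumentState(
        channels,
        rng_seed=int(cfg.get("seed", 0)),
        beep_enabled=bool(cfg.get("beep", True)),
    )
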