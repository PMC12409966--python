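"""Line-oriented text command protocol of the instrument's serial port.

The physical instrument accepts newline-terminated ASCII commands over a
9600-8-N-1 serial link; this module implements the same verbs against a
virtual :class:`~ledspec.instrument.InstrumentState`, both as a pure
per-message handler and as a stream server.

Verbs:

``check``
    Returns ``imhere`` (and, exceptionally, no ``ready``).
``cuvset N``
    Sets the active cuvette position; values other than 1-6 are ignored.
``readabs``
    Returns the absorbance of the active position (3 decimals).
``readi``
    Returns the raw sensor frequency (integer Hz).
``zero`` / ``zeroall``
    Zero the active position / all six positions.
``beep``
    Generates a tone event.
``beepon [off]``
    Turns the beep function off iff the argument is exactly ``off``,
    otherwise on.  The firmware's documented spelling ``beeepon`` is
    accepted as an alias.

Every recognised command other than ``check`` terminates with ``ready``;
unrecognised commands get ``What?``.  Responses are newline-terminated text.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

from .instrument import InstrumentState

__all__ = ["CommandMessage", "Response", "handle_command", "serve", "SERIAL_PARAMS"]

#: Serial-link parameters of the physical instrument, kept as session metadata.
SERIAL_PARAMS = {"baud": 9600, "data_bits": 8, "parity": "none", "stop_bits": 1}

TERMINATOR = "\n"  # ASCII 10

STATUS_READY = "ready"
STATUS_CHECK = "imhere"
STATUS_UNKNOWN = "What?"

_KNOWN_VERBS = {
    "check",
    "cuvset",
    "readabs",
    "readi",
    "zero",
    "zeroall",
    "beep",
    "beepon",
    "beeepon",
}


@dataclass(frozen=True)
class CommandMessage:
    """One parsed command: a verb plus an optional argument token."""

    verb: str
    argument: str | None = None

    @classmethod
    def parse(cls, line: str) -> "CommandMessage":
        """Parse one newline-terminated command line."""
        if not line.endswith(TERMINATOR):
            raise ValueError("command message must end with the newline character (ASCII 10)")
        tokens = line.strip().split()
        verb = tokens[0] if tokens else ""
        argument = tokens[1] if len(tokens) > 1 else None
        return cls(verb=verb, argument=argument)


@dataclass(frozen=True)
class Response:
    """Payload lines plus exactly one terminal status token."""

    payload: tuple[str, ...]
    status: str

    def __post_init__(self) -> None:
        if self.status not in (STATUS_READY, STATUS_CHECK, STATUS_UNKNOWN):
            raise ValueError(f"invalid status token: {self.status!r}")

    def lines(self) -> list[str]:
        return [*self.payload, self.status]

    def text(self) -> str:
        return "".join(line + TERMINATOR for line in self.lines())


def handle_command(
    state: InstrumentState, message: CommandMessage | str
) -> tuple[InstrumentState, Response]:
    """Execute one command against the instrument.

    A pure function of (state, message) given the instrument's RNG stream:
    mutates and returns the state together with the response.
    """
    if isinstance(message, str):
        message = CommandMessage.parse(message)
    verb, arg = message.verb, message.argument
    payload: tuple[str, ...] = ()

    if verb == "check":
        # the one verb that answers with its own token instead of "ready"
        state._log("command", state.active_position, "check")
        return state, Response(payload, STATUS_CHECK)
    if verb not in _KNOWN_VERBS:
        state._log("command", state.active_position, f"unknown:{verb}")
        return state, Response(payload, STATUS_UNKNOWN)

    if verb == "cuvset":
        try:
            n = int(arg) if arg is not None else None
        except ValueError:
            n = None
        if n is not None and 1 <= n <= 6:
            state.active_position = n
        # values other than 1-6 (or junk) are ignored, still "ready"
    elif verb == "readabs":
        payload = (f"{state.read_absorbance():.3f}",)
    elif verb == "readi":
        freq, _ = state.measure_frequency()
        payload = (str(freq),)
    elif verb == "zero":
        state.zero()
    elif verb == "zeroall":
        state.zero_all()
    elif verb == "beep":
        state._log("command", state.active_position, "beep")
    elif verb in ("beepon", "beeepon"):
        state.beep_enabled = arg != "off"
    state._log("command", state.active_position, verb)
    return state, Response(payload, STATUS_READY)


@dataclass
class SessionLog:
    """Transcript of one protocol session: (timestamp, direction, text)."""

    entries: list[tuple[float, str, str]] = field(default_factory=list)
    metadata: dict = field(default_factory=lambda: dict(SERIAL_PARAMS))

    def record(self, direction: str, text: str) -> None:
        self.entries.append((time.time(), direction, text))

    def format(self) -> str:
        return "\n".join(f"{t:.3f}\t{d}\t{x!r}" for t, d, x in self.entries)


def serve(state: InstrumentState, transport_in, transport_out) -> SessionLog:
    """Bind the command handler to a bidirectional text stream.

    Reads newline-delimited commands from ``transport_in``, writes responses
    to ``transport_out``, until the input stream ends.  A trailing partial
    line (no terminator) is never acted on, matching the streaming contract
    of the serial firmware.  All traffic is logged and the (possibly partial)
    log is returned even if the transport fails mid-session.
    """
    log = SessionLog()
    buffer = ""
    try:
        while True:
            chunk = transport_in.read(1)
            if chunk == "":
                break
            buffer += chunk
            while TERMINATOR in buffer:
                line, buffer = buffer.split(TERMINATOR, 1)
                line += TERMINATOR
                log.record("rx", line)
                _, response = handle_command(state, line)
                text = response.text()
                transport_out.write(text)
                if hasattr(transport_out, "flush"):
                    transport_out.flush()
                log.record("tx", text)
    except OSError:
        pass  # transport failure: session ends, partial log preserved
    return log
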