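"""Plain-text readers and writers, plus the JSON run configuration.

Input is deliberately minimal: one numeric value per line, or a
single-column CSV whose header is ``value``.  Series are written back
the same way, with the generating :class:`~msentropy.signals.SignalSpec`
(when known) serialized to a JSON sidecar so every synthetic series
can be regenerated bit-identically.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .exceptions import EmptyInputError, InvalidInputError, ParseError
from .multiscale import MSEParams
from .signals import SignalSpec, TimeSeries

__all__ = ["read_series", "write_series", "RunConfig"]


def read_series(path: str | os.PathLike, label: str = "") -> TimeSeries:
    """Read a single-channel series from plain text or single-column CSV.

    Blank lines are ignored; sample order is preserved.  A lone
    non-numeric first token is accepted as a CSV header; any other
    non-numeric token raises :class:`ParseError` with its line number.
    """
    values: list[float] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            token = raw.strip().strip(",")
            if not token:
                continue
            try:
                value = float(token)
            except ValueError:
                if lineno == 1 and not values:
                    # header line, e.g. "value"
                    continue
                raise ParseError(
                    f"{path}: non-numeric token {token!r} on line {lineno}",
                    line=lineno) from None
            if not np.isfinite(value):
                raise ParseError(
                    f"{path}: non-finite value {token!r} on line {lineno}",
                    line=lineno)
            values.append(value)
    if not values:
        raise EmptyInputError(f"{path}: no numeric values found")
    return TimeSeries(np.asarray(values), label=label or os.fspath(path))


def write_series(ts: TimeSeries, path: str | os.PathLike,
                 sidecar: bool = True) -> None:
    """Write one value per line (CSV with ``value`` header for ``.csv`` paths).

    Values are written with ``repr`` round-trip precision.  When the
    series carries a :class:`SignalSpec` and ``sidecar`` is true, the
    spec is saved next to the data as ``<path>.spec.json``.
    """
    path = os.fspath(path)
    as_csv = path.lower().endswith(".csv")
    with open(path, "w", encoding="utf-8") as fh:
        if as_csv:
            fh.write("value\n")
        for v in ts.values:
            fh.write(f"{float(v)!r}\n")
    if sidecar and ts.spec is not None:
        with open(path + ".spec.json", "w", encoding="utf-8") as fh:
            json.dump(ts.spec.to_dict(), fh, indent=2)
            fh.write("\n")


@dataclass(frozen=True)
class RunConfig:
    """A complete, replayable analysis request.

    Exactly one of ``input_path`` and ``spec`` is set; a seed is
    mandatory when the input is synthetic (it is the spec's seed).
    """

    params: MSEParams
    input_path: Optional[str] = None
    spec: Optional[SignalSpec] = None
    output_path: Optional[str] = None
    log_level: str = "INFO"

    def __post_init__(self):
        if (self.input_path is None) == (self.spec is None):
            raise InvalidInputError(
                "exactly one of input_path and spec must be set")

    @property
    def seed(self) -> Optional[int]:
        return self.spec.seed if self.spec is not None else None

    def load(self) -> TimeSeries:
        from .signals import generate
        if self.spec is not None:
            return generate(self.spec)
        return read_series(self.input_path)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = json.load(fh)
        pd_ = raw.get("params", {})
        params = MSEParams(
            m=int(pd_.get("m", 2)),
            r_factor=float(pd_.get("r_factor", 0.15)),
            scales=tuple(pd_.get("scales", range(1, 21))),
            threshold_mode=pd_.get("threshold_mode", "fixed"),
            normalize_input=bool(pd_.get("normalize_input", True)),
        )
        spec = SignalSpec.from_dict(raw["spec"]) if "spec" in raw else None
        return cls(params=params, input_path=raw.get("input_path"),
                   spec=spec, output_path=raw.get("output_path"),
                   log_level=raw.get("log_level", "INFO"))
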