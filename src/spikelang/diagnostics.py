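"""Validation findings: severity, code, message, source location."""

from __future__ import annotations

import sys
from dataclasses import dataclass
from typing import Optional


@dataclass
class Diagnostic:
    severity: str  # error | warning | info
    code: str  # short identifier, e.g. "unit-mismatch"
    message: str
    location: Optional[tuple[int, int]] = None  # (line, column)
    origin: str = "<memory>"

    def format(self) -> str:
        line, col = self.location if self.location else (0, 0)
        return f"{self.origin}:{line}:{col}: {self.severity} [{self.code}] {self.message}"

    def __str__(self) -> str:
        return self.format()


def print_diagnostics(diags: list[Diagnostic], stream=None) -> None:
    stream = stream if stream is not None else sys.stderr
    for d in diags:
        print(d.format(), file=stream)


def has_errors(diags: list[Diagnostic]) -> bool:
    return any(d.severity == "error" for d in diags)


class ModelError(Exception):
    """A hard failure in a processing stage, carrying one diagnostic."""

    def __init__(self, diagnostic: Diagnostic):
        super().__init__(diagnostic.format())
        self.diagnostic = diagnostic


def error(code: str, message: str, location=None, origin: str = "<memory>") -> ModelError:
    return ModelError(Diagnostic("error", code, message, location, origin))
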