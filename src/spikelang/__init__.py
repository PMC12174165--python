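"""spikelang: a modeling language and simulation toolchain for hybrid
neuron and synapse models.

Models are hybrid dynamical systems: continuous dynamics given as ODEs (with
optional convolution kernels applied to incoming spike trains) plus discrete
event handlers that can jump state variables instantaneously.  The toolchain
parses plain-text model files, checks them statically (names, scopes, and
physical-unit consistency), lowers convolutions and higher-order equations
to a first-order system, solves the linear constant-coefficient part exactly
with propagator matrices, and runs networks of instantiated models in a
time-driven reference simulator.
"""

from importlib import resources

from .ast_nodes import Model
from .diagnostics import Diagnostic, ModelError, has_errors
from .lexer import tokenize
from .parser import parse_model
from .printer import print_model
from .symbols import build_symbol_tables
from .typecheck import infer_type
from .units import (QuantityType, TypeDesc, UnitError, conversion_factor,
                    parse_type, parse_unit)
from .validation import check_model

__version__ = "0.1.0"


def load_model_text(name: str) -> str:
    """Return the source text of a packaged model fixture (e.g. "adex_neuron")."""
    return (resources.files("spikelang") / "models" / f"{name}.sl").read_text()


def load_model(name: str) -> Model:
    """Parse a packaged model fixture by name."""
    return parse_model(load_model_text(name), origin=f"{name}.sl")


__all__ = [
    "Model", "Diagnostic", "ModelError", "has_errors",
    "tokenize", "parse_model", "print_model", "build_symbol_tables",
    "infer_type", "check_model",
    "QuantityType", "TypeDesc", "UnitError", "conversion_factor",
    "parse_type", "parse_unit",
    "load_model", "load_model_text",
    "__version__",
]
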