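"""The 48-function instruction palette.

Every function is *protected*: guarded division, absolute values under
roots and logarithms, clamped exponentials, and boolean operations on
sign-thresholded operands, so any instruction sequence is a total function
of its inputs. Function ids (list positions) are stable and serialised with
models; ``PALETTE_VERSION`` guards against palette drift between a saved
model and the executing code.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

PALETTE_VERSION = 1

#: values are clamped to this magnitude after every instruction
CLAMP = 1.0e6
_EPS = 1.0e-9
_EXP_LIM = 50.0


def _b(x):
    """Threshold an operand to boolean: positive means true."""
    return np.asarray(x) > 0


def _div(a, b):
    b = np.asarray(b, dtype=float)
    return a / np.where(np.abs(b) < _EPS, 1.0, b)


def _mod(a, b):
    b = np.asarray(b, dtype=float)
    return np.mod(a, np.where(np.abs(b) < _EPS, 1.0, b))


def _pow(a, b):
    return np.power(np.abs(a) + _EPS, np.clip(b, -4.0, 4.0))


def _exp(x):
    return np.exp(np.clip(x, -_EXP_LIM, _EXP_LIM))


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -_EXP_LIM, _EXP_LIM)))


def _clip3(x, lo, hi):
    lo, hi = np.minimum(lo, hi), np.maximum(lo, hi)
    return np.clip(x, lo, hi)


@dataclass(frozen=True)
class FunctionSpec:
    name: str
    arity: int
    fn: Callable

    @property
    def needs_nan_guard(self) -> bool:
        return self.name in _NAN_PRONE


# functions whose protected forms can still emit NaN/Inf from extreme finite
# inputs (e.g. 0/eps ratios, inf-inf in expm1 chains); everything else only
# needs the magnitude clamp
_NAN_PRONE = frozenset(
    {"div", "mod", "pow", "inv", "tan", "expm1", "sinh", "cosh", "hypot",
     "exp", "log", "log10", "fma", "mul", "square", "cube", "add", "sub"}
)


PALETTE: tuple[FunctionSpec, ...] = tuple(
    FunctionSpec(name, arity, fn)
    for name, arity, fn in [
        # arithmetic
        ("add", 2, np.add),
        ("sub", 2, np.subtract),
        ("mul", 2, np.multiply),
        ("div", 2, _div),
        ("mod", 2, _mod),
        ("pow", 2, _pow),
        ("min", 2, np.minimum),
        ("max", 2, np.maximum),
        ("hypot", 2, np.hypot),
        ("mean2", 2, lambda a, b: 0.5 * (np.asarray(a, dtype=float) + b)),
        ("absdiff", 2, lambda a, b: np.abs(np.subtract(a, b))),
        # unary transforms
        ("abs", 1, np.abs),
        ("neg", 1, np.negative),
        ("sign", 1, np.sign),
        ("sqrt", 1, lambda x: np.sqrt(np.abs(x))),
        ("square", 1, np.square),
        ("cube", 1, lambda x: np.power(np.asarray(x, dtype=float), 3)),
        ("exp", 1, _exp),
        ("expm1", 1, lambda x: np.expm1(np.clip(x, -_EXP_LIM, _EXP_LIM))),
        ("log", 1, lambda x: np.log(np.abs(x) + _EPS)),
        ("log1p", 1, lambda x: np.log1p(np.abs(x))),
        ("log10", 1, lambda x: np.log10(np.abs(x) + _EPS)),
        ("inv", 1, lambda x: _div(1.0, x)),
        # trigonometric and hyperbolic
        ("sin", 1, np.sin),
        ("cos", 1, np.cos),
        ("tan", 1, np.tan),
        ("sinh", 1, lambda x: np.sinh(np.clip(x, -_EXP_LIM, _EXP_LIM))),
        ("cosh", 1, lambda x: np.cosh(np.clip(x, -_EXP_LIM, _EXP_LIM))),
        ("tanh", 1, np.tanh),
        ("arcsinh", 1, np.arcsinh),
        ("arctan", 1, np.arctan),
        # squashing / activation
        ("sigmoid", 1, _sigmoid),
        ("relu", 1, lambda x: np.maximum(x, 0.0)),
        ("gauss", 1, lambda x: np.exp(-np.square(np.clip(x, -_EXP_LIM, _EXP_LIM)))),
        ("gauss_kernel", 2, lambda a, b: np.exp(-np.square(np.clip(np.subtract(a, b), -_EXP_LIM, _EXP_LIM)))),
        # comparisons (0/1 valued)
        ("gt", 2, lambda a, b: np.greater(a, b).astype(float)),
        ("lt", 2, lambda a, b: np.less(a, b).astype(float)),
        ("ge", 2, lambda a, b: np.greater_equal(a, b).astype(float)),
        ("le", 2, lambda a, b: np.less_equal(a, b).astype(float)),
        ("near", 2, lambda a, b: (np.abs(np.subtract(a, b)) < 1.0).astype(float)),
        # boolean ops on sign-thresholded operands (0/1 valued)
        ("and", 2, lambda a, b: (_b(a) & _b(b)).astype(float)),
        ("or", 2, lambda a, b: (_b(a) | _b(b)).astype(float)),
        ("xor", 2, lambda a, b: (_b(a) ^ _b(b)).astype(float)),
        ("not", 1, lambda x: (~_b(x)).astype(float)),
        # ternary
        ("if_then_else", 3, lambda a, b, c: np.where(_b(a), b, c)),
        ("clip", 3, _clip3),
        ("fma", 3, lambda a, b, c: np.add(a, np.multiply(b, c))),
        ("floor", 1, np.floor),
    ]
)

assert len(PALETTE) == 48
ARITIES = np.array([f.arity for f in PALETTE])


def guard(x):
    """Make an instruction result finite and bounded."""
    return np.clip(np.nan_to_num(x, nan=0.0, posinf=CLAMP, neginf=-CLAMP), -CLAMP, CLAMP)


def guard_clip(x):
    """Magnitude clamp for functions that cannot produce NaN/Inf."""
    return np.clip(x, -CLAMP, CLAMP)
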