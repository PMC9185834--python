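"""Restricted arithmetic expressions in the density variable C.

User-supplied crowding functions can be given as strings such as
``"(1-C)*(1+C/2)"``.  The grammar is deliberately tiny: numbers, the variable
``C``, the binary operators ``+ - * / **``, unary minus, parentheses, and the
whitelisted functions below.  Anything else is rejected at compile time, so
config files can never execute arbitrary code.
"""

from __future__ import annotations

import ast
from typing import Callable

import numpy as np

_FUNCTIONS = {
    "exp": np.exp,
    "log": np.log,
    "log1p": np.log1p,
    "sqrt": np.sqrt,
    "sin": np.sin,
    "cos": np.cos,
    "abs": np.abs,
}

_ALLOWED_BINOPS = (ast.Add, ast.Sub, ast.Mult, ast.Div, ast.Pow)
_ALLOWED_UNARY = (ast.UAdd, ast.USub)


class ExpressionError(ValueError):
    """Raised when an expression falls outside the restricted grammar."""


def _check(node: ast.AST) -> None:
    if isinstance(node, ast.Expression):
        _check(node.body)
    elif isinstance(node, ast.BinOp) and isinstance(node.op, _ALLOWED_BINOPS):
        _check(node.left)
        _check(node.right)
    elif isinstance(node, ast.UnaryOp) and isinstance(node.op, _ALLOWED_UNARY):
        _check(node.operand)
    elif isinstance(node, ast.Constant):
        if not isinstance(node.value, (int, float)):
            raise ExpressionError(f"non-numeric constant {node.value!r}")
    elif isinstance(node, ast.Name):
        if node.id != "C":
            raise ExpressionError(f"unknown name {node.id!r}; only the variable C is allowed")
    elif isinstance(node, ast.Call):
        if not isinstance(node.func, ast.Name) or node.func.id not in _FUNCTIONS:
            raise ExpressionError("only calls to " + ", ".join(sorted(_FUNCTIONS)) + " are allowed")
        if node.keywords or len(node.args) != 1:
            raise ExpressionError("functions take exactly one positional argument")
        _check(node.args[0])
    else:
        raise ExpressionError(f"disallowed syntax: {ast.dump(node)}")


def compile_expression(text: str) -> Callable:
    """Compile a restricted expression into a vectorised function of C."""
    try:
        tree = ast.parse(text, mode="eval")
    except SyntaxError as exc:
        raise ExpressionError(f"cannot parse expression {text!r}: {exc}") from exc
    _check(tree)
    code = compile(tree, "<crowding-expression>", "eval")
    env = {"__builtins__": {}, **_FUNCTIONS}

    def fn(C, _code=code, _env=env):
        return eval(_code, _env, {"C": np.asarray(C, dtype=float)})

    return fn
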