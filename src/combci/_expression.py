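"""Safe arithmetic expressions for combination functions.

Config files and the CLI describe the combination function as a plain
arithmetic expression over named parameters ("pHBsAg * pHDVgivenHBsAg").
The expression is parsed with Python's ``ast`` module and walked against
a whitelist — binary arithmetic, unary sign, parentheses, numeric
literals, parameter names and a handful of elementwise functions — so no
arbitrary code can run from a config file.  Evaluation is vectorized
over numpy arrays of bootstrap draws.
"""

from __future__ import annotations

import ast
from typing import Callable, Mapping, Sequence

import numpy as np

from .errors import ExpressionError

__all__ = ["compile_expression", "expression_names", "ALLOWED_FUNCTIONS"]

ALLOWED_FUNCTIONS: dict[str, Callable] = {
    "exp": np.exp,
    "log": np.log,
    "log2": np.log2,
    "log10": np.log10,
    "sqrt": np.sqrt,
    "abs": np.abs,
}

_BINOPS = {
    ast.Add: np.add,
    ast.Sub: np.subtract,
    ast.Mult: np.multiply,
    ast.Div: np.divide,
    ast.Pow: np.power,
}

_UNARYOPS = {ast.USub: np.negative, ast.UAdd: lambda x: x}


def _parse(text: str) -> ast.Expression:
    try:
        return ast.parse(text, mode="eval")
    except SyntaxError as exc:
        raise ExpressionError(
            f"could not parse expression {text!r}: {exc.msg} at offset {exc.offset}"
        ) from exc


def expression_names(text: str) -> set[str]:
    """All parameter names referenced by the expression (functions excluded)."""
    tree = _parse(text)
    names = set()
    for node in ast.walk(tree):
        if isinstance(node, ast.Name):
            names.add(node.id)
        if isinstance(node, ast.Call) and isinstance(node.func, ast.Name):
            names.discard(node.func.id)
    return names - set(ALLOWED_FUNCTIONS)


def _check(node: ast.AST, known: set[str]) -> None:
    if isinstance(node, ast.Expression):
        _check(node.body, known)
    elif isinstance(node, ast.BinOp):
        if type(node.op) not in _BINOPS:
            raise ExpressionError(f"operator {type(node.op).__name__} not allowed")
        _check(node.left, known)
        _check(node.right, known)
    elif isinstance(node, ast.UnaryOp):
        if type(node.op) not in _UNARYOPS:
            raise ExpressionError(f"operator {type(node.op).__name__} not allowed")
        _check(node.operand, known)
    elif isinstance(node, ast.Call):
        if not isinstance(node.func, ast.Name) or node.func.id not in ALLOWED_FUNCTIONS:
            raise ExpressionError(
                "only these functions are allowed: "
                + ", ".join(sorted(ALLOWED_FUNCTIONS))
            )
        if node.keywords or len(node.args) != 1:
            raise ExpressionError(
                f"{node.func.id}() takes exactly one positional argument"
            )
        _check(node.args[0], known)
    elif isinstance(node, ast.Name):
        if node.id not in known:
            raise ExpressionError(f"unknown parameter name {node.id!r}")
    elif isinstance(node, ast.Constant):
        if not isinstance(node.value, (int, float)):
            raise ExpressionError(f"literal {node.value!r} not allowed")
    else:
        raise ExpressionError(f"syntax element {type(node).__name__} not allowed")


def _evaluate(node: ast.AST, env: Mapping[str, np.ndarray]):
    if isinstance(node, ast.Expression):
        return _evaluate(node.body, env)
    if isinstance(node, ast.BinOp):
        return _BINOPS[type(node.op)](_evaluate(node.left, env), _evaluate(node.right, env))
    if isinstance(node, ast.UnaryOp):
        return _UNARYOPS[type(node.op)](_evaluate(node.operand, env))
    if isinstance(node, ast.Call):
        return ALLOWED_FUNCTIONS[node.func.id](_evaluate(node.args[0], env))
    if isinstance(node, ast.Name):
        return env[node.id]
    return node.value  # ast.Constant


def compile_expression(
    text: str, parameter_names: Sequence[str]
) -> Callable[[Sequence[np.ndarray]], np.ndarray]:
    """Compile an expression into a combination function.

    The returned callable follows the bootstrap engine's contract: it
    takes a sequence of k arrays (or scalars), ordered like
    ``parameter_names``, and returns the elementwise combined value.

    Raises :class:`ExpressionError` on parse failure, disallowed syntax,
    names not present in ``parameter_names``, or duplicated parameter
    names.
    """
    names = list(parameter_names)
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ExpressionError(f"duplicate parameter names: {sorted(dupes)}")
    tree = _parse(text)
    _check(tree, set(names))
    used = expression_names(text)
    unused = set(names) - used
    if unused:
        raise ExpressionError(
            f"parameters never used in the expression: {sorted(unused)}"
        )

    def comb(values: Sequence[np.ndarray]):
        env = dict(zip(names, values))
        return _evaluate(tree, env)

    return comb
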