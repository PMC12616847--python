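"""Assertion mini-language: a closed, side-effect-free expression grammar.

``then`` blocks in native suites are written in a small expression language
rather than a general-purpose one: no loops, no assignment, no attribute
mutation, no arbitrary code execution.  Supported forms::

    out.exit_status == 0
    out.channels["versions"] | size == 1
    "WARN" in out.stderr
    out.files contains "report.html"
    vcf.summary(out.files[0]).variant_count == 3
    a and not b or c

Operators: ``== != < <= > >= in contains and or not``.  The pipe ``x | f``
applies a registered unary function ``f`` to ``x`` and binds tighter than
comparison, so ``ch | size == 1`` reads "size of ch equals 1".
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Any, Callable, Optional

from pipetest.model import SpecError

# ---------------------------------------------------------------- lexer

_TOKEN_RE = re.compile(
    r"""
    (?P<ws>\s+)
  | (?P<number>\d+\.\d+(?:[eE][+-]?\d+)?|\d+[eE][+-]?\d+|\d+)
  | (?P<string>"(?:[^"\\]|\\.)*"|'(?:[^'\\]|\\.)*')
  | (?P<name>[A-Za-z_][A-Za-z0-9_]*)
  | (?P<op>==|!=|<=|>=|<|>|\||\(|\)|\[|\]|\.|,)
    """,
    re.VERBOSE,
)

_KEYWORDS = {"and", "or", "not", "in", "contains", "true", "false", "null"}


@dataclass(frozen=True)
class Token:
    kind: str  # number | string | name | op | keyword | end
    text: str
    pos: int


def tokenize(source: str) -> list[Token]:
    tokens: list[Token] = []
    pos = 0
    while pos < len(source):
        m = _TOKEN_RE.match(source, pos)
        if m is None:
            raise SpecError(
                f"unexpected character {source[pos]!r} at column {pos + 1} "
                f"in assertion {source!r}")
        pos = m.end()
        kind = m.lastgroup
        if kind == "ws":
            continue
        text = m.group()
        if kind == "name" and text in _KEYWORDS:
            kind = "keyword"
        tokens.append(Token(kind, text, m.start()))
    tokens.append(Token("end", "", len(source)))
    return tokens


# ----------------------------------------------------------------- AST

@dataclass(frozen=True)
class Literal:
    value: Any


@dataclass(frozen=True)
class Name:
    ident: str


@dataclass(frozen=True)
class Member:
    obj: Any
    attr: str


@dataclass(frozen=True)
class Index:
    obj: Any
    key: Any


@dataclass(frozen=True)
class Call:
    func: Any
    args: tuple


@dataclass(frozen=True)
class Pipe:
    obj: Any
    func: str


@dataclass(frozen=True)
class Compare:
    op: str  # == != < <= > >= in contains
    left: Any
    right: Any


@dataclass(frozen=True)
class BoolOp:
    op: str  # and | or
    operands: tuple


@dataclass(frozen=True)
class Not:
    operand: Any


@dataclass(frozen=True)
class ListExpr:
    items: tuple


@dataclass
class AssertionExpr:
    """A parsed assertion: original source plus its expression tree."""

    source: str
    ast: Any = None

    def __post_init__(self):
        if self.ast is None:
            self.ast = _Parser(self.source).parse()


# -------------------------------------------------------------- parser

_COMPARE_OPS = {"==", "!=", "<", "<=", ">", ">=", "in", "contains"}


class _Parser:
    def __init__(self, source: str):
        self.source = source
        self.tokens = tokenize(source)
        self.i = 0

    def peek(self) -> Token:
        return self.tokens[self.i]

    def advance(self) -> Token:
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def expect(self, text: str) -> Token:
        tok = self.advance()
        if tok.text != text:
            self.fail(f"expected {text!r}, found {tok.text or 'end'!r}", tok)
        return tok

    def fail(self, msg: str, tok: Optional[Token] = None):
        tok = tok or self.peek()
        raise SpecError(
            f"{msg} at column {tok.pos + 1} in assertion {self.source!r}")

    def parse(self) -> Any:
        node = self.or_expr()
        if self.peek().kind != "end":
            self.fail(f"unexpected trailing {self.peek().text!r}")
        return node

    def or_expr(self) -> Any:
        operands = [self.and_expr()]
        while self.peek().text == "or":
            self.advance()
            operands.append(self.and_expr())
        return operands[0] if len(operands) == 1 else BoolOp("or", tuple(operands))

    def and_expr(self) -> Any:
        operands = [self.not_expr()]
        while self.peek().text == "and":
            self.advance()
            operands.append(self.not_expr())
        return operands[0] if len(operands) == 1 else BoolOp("and", tuple(operands))

    def not_expr(self) -> Any:
        if self.peek().text == "not":
            self.advance()
            return Not(self.not_expr())
        return self.comparison()

    def comparison(self) -> Any:
        left = self.pipe_expr()
        tok = self.peek()
        if tok.text in _COMPARE_OPS:
            self.advance()
            right = self.pipe_expr()
            return Compare(tok.text, left, right)
        return left

    def pipe_expr(self) -> Any:
        node = self.postfix()
        while self.peek().text == "|":
            self.advance()
            tok = self.advance()
            if tok.kind != "name":
                self.fail("pipe target must be a function name", tok)
            node = Pipe(node, tok.text)
        return node

    def postfix(self) -> Any:
        node = self.atom()
        while True:
            tok = self.peek()
            if tok.text == ".":
                self.advance()
                attr = self.advance()
                if attr.kind != "name":
                    self.fail("expected attribute name after '.'", attr)
                node = Member(node, attr.text)
            elif tok.text == "[":
                self.advance()
                key = self.or_expr()
                self.expect("]")
                node = Index(node, key)
            elif tok.text == "(":
                self.advance()
                args: list[Any] = []
                if self.peek().text != ")":
                    args.append(self.or_expr())
                    while self.peek().text == ",":
                        self.advance()
                        args.append(self.or_expr())
                self.expect(")")
                node = Call(node, tuple(args))
            else:
                return node

    def atom(self) -> Any:
        tok = self.advance()
        if tok.kind == "number":
            text = tok.text
            if re.fullmatch(r"\d+", text):
                return Literal(int(text))
            return Literal(float(text))
        if tok.kind == "string":
            body = tok.text[1:-1]
            return Literal(re.sub(r"\\(.)", r"\1", body))
        if tok.kind == "keyword":
            if tok.text == "true":
                return Literal(True)
            if tok.text == "false":
                return Literal(False)
            if tok.text == "null":
                return Literal(None)
            self.fail(f"keyword {tok.text!r} cannot start an expression", tok)
        if tok.kind == "name":
            return Name(tok.text)
        if tok.text == "(":
            node = self.or_expr()
            self.expect(")")
            return node
        if tok.text == "[":
            items: list[Any] = []
            if self.peek().text != "]":
                items.append(self.or_expr())
                while self.peek().text == ",":
                    self.advance()
                    items.append(self.or_expr())
            self.expect("]")
            return ListExpr(tuple(items))
        self.fail(f"unexpected {tok.text or 'end'!r}", tok)


# ------------------------------------------------------------ evaluator

class EvalError(Exception):
    """Evaluation failed in a way that makes the assertion *errored*
    (unknown namespace, plugin raised) rather than merely false."""


class AssertionFailure(Exception):
    """Evaluation produced a definite failure with a message (e.g. a
    reference to a channel the unit never emitted)."""


_BUILTIN_PIPES: dict[str, Callable[[Any], Any]] = {
    "size": lambda v: len(v),
    "length": lambda v: len(v),
    "sorted": lambda v: sorted(v),
    "sum": lambda v: sum(v),
    "min": lambda v: min(v),
    "max": lambda v: max(v),
    "first": lambda v: v[0],
    "last": lambda v: v[-1],
    "flatten": lambda v: [x for item in v for x in
                          (item if isinstance(item, (list, tuple)) else [item])],
    "unique": lambda v: sorted(set(v)),
    "text": lambda v: str(v),
}


@dataclass
class Environment:
    """Name bindings and plugin namespaces visible to assertions."""

    names: dict[str, Any] = field(default_factory=dict)
    namespaces: dict[str, dict[str, Callable]] = field(default_factory=dict)
    pipes: dict[str, Callable[[Any], Any]] = field(default_factory=dict)

    def pipe_fn(self, name: str) -> Callable[[Any], Any]:
        if name in self.pipes:
            return self.pipes[name]
        if name in _BUILTIN_PIPES:
            return _BUILTIN_PIPES[name]
        raise EvalError(f"unknown pipe function {name!r}")


class _NamespaceRef:
    __slots__ = ("name", "functions")

    def __init__(self, name: str, functions: dict[str, Callable]):
        self.name = name
        self.functions = functions


def evaluate(node: Any, env: Environment) -> Any:
    if isinstance(node, AssertionExpr):
        return evaluate(node.ast, env)
    if isinstance(node, Literal):
        return node.value
    if isinstance(node, ListExpr):
        return [evaluate(item, env) for item in node.items]
    if isinstance(node, Name):
        if node.ident in env.names:
            return env.names[node.ident]
        if node.ident in env.namespaces:
            return _NamespaceRef(node.ident, env.namespaces[node.ident])
        raise EvalError(f"unknown name {node.ident!r}")
    if isinstance(node, Member):
        obj = evaluate(node.obj, env)
        return _member(obj, node.attr)
    if isinstance(node, Index):
        obj = evaluate(node.obj, env)
        key = evaluate(node.key, env)
        return _index(obj, key)
    if isinstance(node, Call):
        func = evaluate(node.func, env)
        args = [evaluate(a, env) for a in node.args]
        if not callable(func):
            raise EvalError(f"value {func!r} is not callable")
        try:
            return func(*args)
        except (EvalError, AssertionFailure):
            raise
        except Exception as exc:  # plugin contract violation
            raise EvalError(f"plugin call failed: {exc}") from exc
    if isinstance(node, Pipe):
        value = evaluate(node.obj, env)
        fn = env.pipe_fn(node.func)
        try:
            return fn(value)
        except (EvalError, AssertionFailure):
            raise
        except Exception as exc:
            raise EvalError(f"pipe {node.func!r} failed: {exc}") from exc
    if isinstance(node, Compare):
        left = evaluate(node.left, env)
        right = evaluate(node.right, env)
        return _compare(node.op, left, right)
    if isinstance(node, BoolOp):
        if node.op == "and":
            result = True
            for operand in node.operands:
                result = bool(evaluate(operand, env))
                if not result:
                    return False
            return result
        for operand in node.operands:
            if bool(evaluate(operand, env)):
                return True
        return False
    if isinstance(node, Not):
        return not bool(evaluate(node.operand, env))
    raise EvalError(f"cannot evaluate node {node!r}")


def _member(obj: Any, attr: str) -> Any:
    if isinstance(obj, _NamespaceRef):
        if attr not in obj.functions:
            raise EvalError(
                f"unknown function {attr!r} in namespace {obj.name!r}")
        return obj.functions[attr]
    if isinstance(obj, dict):
        if attr in obj:
            return obj[attr]
        raise AssertionFailure(f"missing key {attr!r}")
    if hasattr(obj, attr) and not attr.startswith("_"):
        value = getattr(obj, attr)
        if callable(value) and not isinstance(value, _NamespaceRef):
            # only plain data attributes are exposed; bound methods are not
            # part of the closed grammar
            raise EvalError(f"attribute {attr!r} is not a data attribute")
        return value
    raise AssertionFailure(f"object has no attribute {attr!r}")


def _index(obj: Any, key: Any) -> Any:
    from pipetest.channels import ChannelMap  # local import, no cycle at load
    if isinstance(obj, ChannelMap):
        return obj[key]
    try:
        return obj[key]
    except (KeyError, IndexError, TypeError) as exc:
        raise AssertionFailure(f"bad index {key!r}: {exc}") from exc


def _compare(op: str, left: Any, right: Any) -> bool:
    if op == "==":
        return left == right
    if op == "!=":
        return left != right
    if op == "in":
        return left in right
    if op == "contains":
        return right in left
    try:
        if op == "<":
            return left < right
        if op == "<=":
            return left <= right
        if op == ">":
            return left > right
        if op == ">=":
            return left >= right
    except TypeError as exc:
        raise EvalError(f"cannot compare {left!r} {op} {right!r}") from exc
    raise EvalError(f"unknown comparison {op!r}")
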