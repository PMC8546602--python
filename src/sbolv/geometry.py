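"""SVG path-data parsing, parametric template evaluation, bounds and transforms.

Path data is restricted to the absolute commands ``M L C Q A Z`` (their
relative lowercase forms are accepted on input and normalized to absolute).
This covers every shape in the bundled glyph library while keeping the
evaluator small; ``H V S T`` shorthands are deliberately unsupported.

Parametric path templates are ordinary path-data strings in which any
number may be replaced by an ``{expression}`` in curly braces, e.g.::

    M {0} {0} L {width - arrowhead_width} {-height}

Evaluating a template against a parameter binding yields plain path data.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

from .errors import PathDataError
from .expressions import evaluate, list_parameters, parse_expression

__all__ = [
    "PathCommand",
    "Bounds",
    "Transform2D",
    "parse_path_data",
    "serialize_path_data",
    "format_number",
    "evaluate_template",
    "template_parameters",
    "path_bounds",
    "apply_transform",
]

#: number of coordinate arguments per opcode (A: rx ry rot large sweep x y)
ARITY = {"M": 2, "L": 2, "C": 6, "Q": 4, "A": 7, "Z": 0}


@dataclass(frozen=True)
class PathCommand:
    """One absolute SVG path command."""

    op: str
    args: tuple[float, ...] = ()

    def __post_init__(self):
        if self.op not in ARITY:
            raise PathDataError(f"unsupported opcode {self.op!r}")
        if len(self.args) != ARITY[self.op]:
            raise PathDataError(
                f"opcode {self.op!r} takes {ARITY[self.op]} arguments, "
                f"got {len(self.args)}"
            )

    @property
    def end(self) -> tuple[float, float] | None:
        """End point of the command (None for Z)."""
        if self.op == "Z":
            return None
        return (self.args[-2], self.args[-1])


@dataclass(frozen=True)
class Bounds:
    """Axis-aligned bounding rectangle (closed intervals)."""

    xmin: float
    ymin: float
    xmax: float
    ymax: float

    def __post_init__(self):
        if self.xmin > self.xmax or self.ymin > self.ymax:
            raise ValueError(f"inverted bounds: {self}")

    @property
    def width(self) -> float:
        return self.xmax - self.xmin

    @property
    def height(self) -> float:
        return self.ymax - self.ymin

    @property
    def center(self) -> tuple[float, float]:
        return ((self.xmin + self.xmax) / 2, (self.ymin + self.ymax) / 2)

    def union(self, other: "Bounds") -> "Bounds":
        return Bounds(
            min(self.xmin, other.xmin),
            min(self.ymin, other.ymin),
            max(self.xmax, other.xmax),
            max(self.ymax, other.ymax),
        )

    def contains(self, other: "Bounds", tol: float = 0.0) -> bool:
        return (
            other.xmin >= self.xmin - tol
            and other.ymin >= self.ymin - tol
            and other.xmax <= self.xmax + tol
            and other.ymax <= self.ymax + tol
        )

    def expanded(self, margin: float) -> "Bounds":
        return Bounds(
            self.xmin - margin, self.ymin - margin, self.xmax + margin, self.ymax + margin
        )


class Transform2D:
    """Invertible planar affine transform ``(x, y) -> (ax + by + e, cx + dy + f)``."""

    __slots__ = ("a", "b", "c", "d", "e", "f")

    def __init__(self, a, b, c, d, e, f):
        if abs(a * d - b * c) < 1e-12:
            raise ValueError("transform is singular")
        self.a, self.b, self.c, self.d, self.e, self.f = a, b, c, d, e, f

    @classmethod
    def identity(cls) -> "Transform2D":
        return cls(1, 0, 0, 1, 0, 0)

    @classmethod
    def translation(cls, dx: float, dy: float) -> "Transform2D":
        return cls(1, 0, 0, 1, dx, dy)

    @classmethod
    def rotation(cls, angle: float, cx: float = 0.0, cy: float = 0.0) -> "Transform2D":
        """Rotation by *angle* radians about (cx, cy)."""
        ca, sa = math.cos(angle), math.sin(angle)
        # exact half-turns matter for the reverse-orientation involution
        if angle == math.pi or angle == -math.pi:
            ca, sa = -1.0, 0.0
        return cls(ca, -sa, sa, ca, cx - ca * cx + sa * cy, cy - sa * cx - ca * cy)

    @classmethod
    def point_reflection(cls, cx: float, cy: float) -> "Transform2D":
        """180-degree rotation about (cx, cy); exact (no trigonometry)."""
        return cls(-1, 0, 0, -1, 2 * cx, 2 * cy)

    @classmethod
    def mirror_x(cls, axis_x: float = 0.0) -> "Transform2D":
        """Reflection across the vertical line x = axis_x."""
        return cls(-1, 0, 0, 1, 2 * axis_x, 0)

    @classmethod
    def mirror_y(cls, axis_y: float = 0.0) -> "Transform2D":
        """Reflection across the horizontal line y = axis_y."""
        return cls(1, 0, 0, -1, 0, 2 * axis_y)

    @property
    def det(self) -> float:
        return self.a * self.d - self.b * self.c

    def is_translation(self) -> bool:
        return (self.a, self.b, self.c, self.d) == (1, 0, 0, 1)

    def is_similarity(self, tol: float = 1e-12) -> bool:
        """True if the linear part is a uniform scale times rotation/reflection."""
        col_diff = (self.a**2 + self.c**2) - (self.b**2 + self.d**2)
        dot = self.a * self.b + self.c * self.d
        scale = abs(self.det)
        return abs(col_diff) <= tol * max(1.0, scale) and abs(dot) <= tol * max(1.0, scale)

    def apply(self, x: float, y: float) -> tuple[float, float]:
        return (self.a * x + self.b * y + self.e, self.c * x + self.d * y + self.f)

    def apply_bounds(self, b: Bounds) -> Bounds:
        corners = [
            self.apply(b.xmin, b.ymin),
            self.apply(b.xmax, b.ymin),
            self.apply(b.xmin, b.ymax),
            self.apply(b.xmax, b.ymax),
        ]
        xs = [p[0] for p in corners]
        ys = [p[1] for p in corners]
        return Bounds(min(xs), min(ys), max(xs), max(ys))

    def __matmul__(self, other: "Transform2D") -> "Transform2D":
        """Composition: (self @ other)(p) == self(other(p))."""
        return Transform2D(
            self.a * other.a + self.b * other.c,
            self.a * other.b + self.b * other.d,
            self.c * other.a + self.d * other.c,
            self.c * other.b + self.d * other.d,
            self.a * other.e + self.b * other.f + self.e,
            self.c * other.e + self.d * other.f + self.f,
        )

    def __repr__(self):
        return (
            f"Transform2D({self.a}, {self.b}, {self.c}, {self.d}, {self.e}, {self.f})"
        )


# ---------------------------------------------------------------------------
# parsing and serialization

_NUM_RE = re.compile(r"[-+]?(?:\d+(?:\.\d*)?|\.\d+)(?:[eE][-+]?\d+)?")
_SEP_RE = re.compile(r"[\s,]*")


def parse_path_data(d: str) -> list[PathCommand]:
    """Parse SVG path data into a list of absolute :class:`PathCommand`.

    Relative (lowercase) opcodes are normalized to absolute.  Arguments may
    be separated by whitespace or commas.  Implicit command repetition is
    supported (an ``M`` repeats as ``L``, per the SVG specification).
    """
    if not d or not d.strip():
        raise PathDataError("empty path data")
    pos = 0
    n = len(d)
    commands: list[PathCommand] = []
    cur = (0.0, 0.0)
    subpath_start = (0.0, 0.0)
    op: str | None = None
    first = True

    def skip_sep(p: int) -> int:
        return _SEP_RE.match(d, p).end()

    pos = skip_sep(pos)
    while pos < n:
        ch = d[pos]
        if ch.isalpha():
            if ch.upper() not in ARITY:
                raise PathDataError(f"unknown opcode {ch!r}", pos)
            op = ch
            pos = skip_sep(pos + 1)
            if op.upper() == "Z":
                commands.append(PathCommand("Z"))
                cur = subpath_start
                op = None
                continue
        elif op is None:
            raise PathDataError(f"expected opcode, found {ch!r}", pos)

        upper = op.upper()
        relative = op.islower() and not (first and upper == "M")
        arity = ARITY[upper]
        args: list[float] = []
        for i in range(arity):
            m = _NUM_RE.match(d, pos)
            if m is None:
                raise PathDataError(
                    f"opcode {op!r} expects {arity} numbers, got {i}", pos
                )
            args.append(float(m.group()))
            pos = skip_sep(m.end())

        if upper == "A":
            rx, ry, rot, large, sweep, x, y = args
            if large not in (0.0, 1.0) or sweep not in (0.0, 1.0):
                raise PathDataError("arc flags must be 0 or 1", pos)
            if relative:
                x += cur[0]
                y += cur[1]
            cmd = PathCommand("A", (rx, ry, rot, large, sweep, x, y))
        else:
            if relative:
                args = [
                    v + (cur[0] if i % 2 == 0 else cur[1]) for i, v in enumerate(args)
                ]
            cmd = PathCommand(upper, tuple(args))
        commands.append(cmd)
        cur = cmd.end
        if upper == "M":
            subpath_start = cur
            # implicit continuation of a moveto is a lineto
            op = "l" if op.islower() else "L"
        first = False

    if not commands or commands[0].op != "M":
        raise PathDataError("path data must start with an M command")
    return commands


def format_number(v: float) -> str:
    """Shortest decimal that round-trips *v*; at most 9 significant digits
    when that is enough to round-trip."""
    if v == int(v) and abs(v) < 1e15:
        return str(int(v))
    s = f"{v:.9g}"
    if float(s) != v:
        s = repr(v)
    return s


def serialize_path_data(commands: list[PathCommand]) -> str:
    """Serialize commands to path data with space-separated arguments."""
    parts = []
    for cmd in commands:
        parts.append(cmd.op)
        parts.extend(format_number(a) for a in cmd.args)
    return " ".join(parts)


# ---------------------------------------------------------------------------
# parametric templates

def _iter_template(template: str):
    """Yield ('text', s) and ('expr', s, pos) chunks of a template."""
    pos = 0
    n = len(template)
    while pos < n:
        open_at = template.find("{", pos)
        close_at = template.find("}", pos)
        if open_at == -1:
            if close_at != -1:
                raise PathDataError("unmatched '}' in template", close_at)
            yield ("text", template[pos:], pos)
            return
        if close_at != -1 and close_at < open_at:
            raise PathDataError("unmatched '}' in template", close_at)
        if open_at > pos:
            yield ("text", template[pos:open_at], pos)
        close_at = template.find("}", open_at + 1)
        inner_open = template.find("{", open_at + 1)
        if inner_open != -1 and (close_at == -1 or inner_open < close_at):
            raise PathDataError("nested '{' in template", inner_open)
        if close_at == -1:
            raise PathDataError("unclosed '{' in template", open_at)
        yield ("expr", template[open_at + 1 : close_at], open_at)
        pos = close_at + 1


def evaluate_template(template: str, binding: dict[str, float]) -> str:
    """Replace every ``{expression}`` in *template* with its numeric value.

    The result parses as plain path data.  Raises
    :class:`~sbolv.errors.EvaluationError` for unbound parameters and
    :class:`~sbolv.errors.PathDataError` for malformed braces.
    """
    out = []
    for chunk in _iter_template(template):
        if chunk[0] == "text":
            out.append(chunk[1])
        else:
            out.append(format_number(evaluate(parse_expression(chunk[1]), binding)))
    return "".join(out)


def template_parameters(template: str) -> set[str]:
    """Set of parameter names referenced by all expressions in *template*."""
    names: set[str] = set()
    for chunk in _iter_template(template):
        if chunk[0] == "expr":
            names |= list_parameters(parse_expression(chunk[1]))
    return names


# ---------------------------------------------------------------------------
# bounds

def _cubic_axis_extrema(p0, p1, p2, p3):
    """Interior parameter values where a cubic Bezier axis component peaks."""
    u, v, w = p1 - p0, p2 - p1, p3 - p2
    a = u - 2 * v + w
    b = 2 * (v - u)
    c = u
    roots = []
    if abs(a) < 1e-300:
        if b != 0:
            roots.append(-c / b)
    else:
        disc = b * b - 4 * a * c
        if disc >= 0:
            sq = math.sqrt(disc)
            roots.append((-b + sq) / (2 * a))
            roots.append((-b - sq) / (2 * a))
    return [t for t in roots if 0.0 < t < 1.0]


def _cubic_point(t, p0, p1, p2, p3):
    s = 1 - t
    return s**3 * p0 + 3 * s**2 * t * p1 + 3 * s * t**2 * p2 + t**3 * p3


def _arc_center(start, cmd_args):
    """Endpoint -> center parametrization of an elliptical arc.

    Returns (cx, cy, rx, ry, phi, theta1, dtheta) or None when the arc is
    degenerate (coincident endpoints or zero radius: treated as a line).
    """
    x1, y1 = start
    rx, ry, rot_deg, large, sweep, x2, y2 = cmd_args
    if (x1, y1) == (x2, y2):
        return None
    rx, ry = abs(rx), abs(ry)
    if rx == 0 or ry == 0:
        return None
    phi = math.radians(rot_deg)
    cphi, sphi = math.cos(phi), math.sin(phi)
    dx, dy = (x1 - x2) / 2, (y1 - y2) / 2
    x1p = cphi * dx + sphi * dy
    y1p = -sphi * dx + cphi * dy
    lam = x1p**2 / rx**2 + y1p**2 / ry**2
    if lam > 1:
        scale = math.sqrt(lam)
        rx *= scale
        ry *= scale
    num = rx**2 * ry**2 - rx**2 * y1p**2 - ry**2 * x1p**2
    den = rx**2 * y1p**2 + ry**2 * x1p**2
    coef = math.sqrt(max(0.0, num / den))
    if large == sweep:
        coef = -coef
    cxp = coef * rx * y1p / ry
    cyp = -coef * ry * x1p / rx
    cx = cphi * cxp - sphi * cyp + (x1 + x2) / 2
    cy = sphi * cxp + cphi * cyp + (y1 + y2) / 2
    theta1 = math.atan2((y1p - cyp) / ry, (x1p - cxp) / rx)
    theta2 = math.atan2((-y1p - cyp) / ry, (-x1p - cxp) / rx)
    dtheta = theta2 - theta1
    if sweep == 0 and dtheta > 0:
        dtheta -= 2 * math.pi
    elif sweep == 1 and dtheta < 0:
        dtheta += 2 * math.pi
    return cx, cy, rx, ry, phi, theta1, dtheta


def _arc_to_cubics(start, cmd: PathCommand) -> list[PathCommand]:
    """Approximate an arc by cubic segments spanning at most pi/2 each."""
    center = _arc_center(start, cmd.args)
    end = (cmd.args[5], cmd.args[6])
    if center is None:
        return [PathCommand("L", end)]
    cx, cy, rx, ry, phi, theta1, dtheta = center
    cphi, sphi = math.cos(phi), math.sin(phi)

    def point(th):
        ct, st = math.cos(th), math.sin(th)
        return (
            cx + rx * ct * cphi - ry * st * sphi,
            cy + rx * ct * sphi + ry * st * cphi,
        )

    def deriv(th):
        ct, st = math.cos(th), math.sin(th)
        return (
            -rx * st * cphi - ry * ct * sphi,
            -rx * st * sphi + ry * ct * cphi,
        )

    n_seg = max(1, math.ceil(abs(dtheta) / (math.pi / 2)))
    step = dtheta / n_seg
    alpha = 4 / 3 * math.tan(step / 4)
    out = []
    th = theta1
    p_start = point(th)
    for i in range(n_seg):
        th_end = theta1 + (i + 1) * step
        p_end = point(th_end) if i < n_seg - 1 else end
        d1 = deriv(th)
        d2 = deriv(th_end)
        out.append(
            PathCommand(
                "C",
                (
                    p_start[0] + alpha * d1[0],
                    p_start[1] + alpha * d1[1],
                    p_end[0] - alpha * d2[0],
                    p_end[1] - alpha * d2[1],
                    p_end[0],
                    p_end[1],
                ),
            )
        )
        th = th_end
        p_start = p_end
    return out


def path_bounds(commands: list[PathCommand]) -> Bounds:
    """Tight axis-aligned bounds of the traced geometry.

    Cubic and quadratic curves are bounded by derivative extremum analysis;
    arcs are converted to cubic segments first.
    """
    if not commands:
        raise PathDataError("cannot compute bounds of an empty command list")
    xs: list[float] = []
    ys: list[float] = []
    cur = (0.0, 0.0)
    subpath_start = (0.0, 0.0)
    for cmd in commands:
        if cmd.op == "Z":
            cur = subpath_start
            continue
        if cmd.op == "M":
            cur = cmd.end
            subpath_start = cur
            xs.append(cur[0])
            ys.append(cur[1])
            continue
        if cmd.op == "L":
            cur = cmd.end
            xs.append(cur[0])
            ys.append(cur[1])
            continue
        if cmd.op == "A":
            for sub in _arc_to_cubics(cur, cmd):
                if sub.op == "C":
                    _accumulate_cubic(cur, sub.args, xs, ys)
                cur = sub.end
                xs.append(cur[0])
                ys.append(cur[1])
            continue
        if cmd.op == "Q":
            cx, cy, x, y = cmd.args
            # elevate to cubic so one extremum routine serves both
            c1 = (cur[0] + 2 / 3 * (cx - cur[0]), cur[1] + 2 / 3 * (cy - cur[1]))
            c2 = (x + 2 / 3 * (cx - x), y + 2 / 3 * (cy - y))
            _accumulate_cubic(cur, (*c1, *c2, x, y), xs, ys)
            cur = (x, y)
            xs.append(x)
            ys.append(y)
            continue
        # C
        _accumulate_cubic(cur, cmd.args, xs, ys)
        cur = cmd.end
        xs.append(cur[0])
        ys.append(cur[1])
    return Bounds(min(xs), min(ys), max(xs), max(ys))


def _accumulate_cubic(start, args, xs, ys):
    x1, y1, x2, y2, x3, y3 = args
    for t in _cubic_axis_extrema(start[0], x1, x2, x3):
        xs.append(_cubic_point(t, start[0], x1, x2, x3))
    for t in _cubic_axis_extrema(start[1], y1, y2, y3):
        ys.append(_cubic_point(t, start[1], y1, y2, y3))


# ---------------------------------------------------------------------------
# transforms

def apply_transform(commands: list[PathCommand], t: Transform2D) -> list[PathCommand]:
    """Map every coordinate of *commands* through *t*.

    Arc radii and axis rotation are adjusted exactly when *t* is a
    similarity (translation, rotation, reflection, uniform scale); for a
    general affine transform arcs are converted to cubic segments first.
    """
    out: list[PathCommand] = []
    cur = (0.0, 0.0)
    similarity = t.is_similarity()
    scale = math.sqrt(abs(t.det))
    for cmd in commands:
        if cmd.op == "Z":
            out.append(cmd)
            continue
        if cmd.op == "A":
            if not similarity:
                for sub in _arc_to_cubics(cur, cmd):
                    out.append(_map_plain(sub, t))
                cur = cmd.end
                continue
            rx, ry, rot_deg, large, sweep, x, y = cmd.args
            if t.is_translation():
                new_rot = rot_deg
                new_sweep = sweep
                new_rx, new_ry = rx, ry
            else:
                phi = math.radians(rot_deg)
                # image of the ellipse x-axis direction under the linear part
                ux, uy = math.cos(phi), math.sin(phi)
                vx = t.a * ux + t.b * uy
                vy = t.c * ux + t.d * uy
                new_rot = math.degrees(math.atan2(vy, vx))
                new_sweep = sweep if t.det > 0 else 1.0 - sweep
                new_rx, new_ry = rx * scale, ry * scale
            nx, ny = t.apply(x, y)
            out.append(
                PathCommand("A", (new_rx, new_ry, new_rot, large, new_sweep, nx, ny))
            )
            cur = cmd.end
            continue
        out.append(_map_plain(cmd, t))
        if cmd.end is not None:
            cur = cmd.end
    return out


def _map_plain(cmd: PathCommand, t: Transform2D) -> PathCommand:
    args = cmd.args
    new = []
    for i in range(0, len(args), 2):
        new.extend(t.apply(args[i], args[i + 1]))
    return PathCommand(cmd.op, tuple(new))
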