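"""Symbolic network with multiplication and division units.

Each hidden layer forms two learned affine combinations (eta_i, xi_i) of the
running channel list and appends either their product (multiplication unit)
or their quotient (division unit); the output is an affine read-out of the
final channel list.  Because every unit is algebraic, the trained network
expands exactly into a closed-form expression: a polynomial part plus
rational terms (linear-over-quadratic under the library constraints), a
trainable fractional power u^alpha with alpha = 1.5 + 0.5 sin(eta) in [1, 2],
and products with the spatial integral channel.

Structural masks implement the a-priori modeling constraints: derivative
channels never feed nonlinear units, division numerators are linear in one
species and denominators quadratic in the other.  Masked weights are exactly
zero and are not trainable parameters at all, so their gradients vanish
identically.

The forward pass is generic over the value type of the channels: numpy
arrays (inference), autodiff tensors (training), or sympy expressions
(exact symbolic expansion).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield
from fractions import Fraction

import numpy as np
import sympy as sp

from . import autodiff as ad

__all__ = [
    "LayerSpec",
    "SymNetParameters",
    "SymbolicTerm",
    "SymbolicModel",
    "symnet_forward",
    "alpha_from_eta",
    "symnet_to_expression",
    "count_parameters",
    "pack_parameters",
    "unpack_parameters",
    "worked_example_params",
    "generic_symnet",
    "example1_symnet",
    "example2_symnet_f1",
    "example2_symnet_f2",
    "example2_symnet_baseline",
    "CHANNEL_SYMBOLS",
]

DIV_EPS = 1e-6
DIV_PENALTY_FLOOR = 1e-3

# sympy atoms for every channel name used by the built-in libraries
CHANNEL_SYMBOLS = {
    "u": sp.Symbol("u"),
    "v": sp.Symbol("v"),
    "ux": sp.Symbol("u_x"),
    "uxx": sp.Symbol("u_xx"),
    "uyy": sp.Symbol("u_yy"),
    "vx": sp.Symbol("v_x"),
    "vxx": sp.Symbol("v_xx"),
    "vyy": sp.Symbol("v_yy"),
    "u2": sp.Symbol("u") ** 2,
    "v2": sp.Symbol("v") ** 2,
    "ualpha": sp.Symbol("u_alpha"),
    "I": sp.Symbol("I_int"),
}


def alpha_from_eta(eta: float):
    """Exponent reparameterization keeping alpha in [1, 2] for any real eta."""
    if isinstance(eta, ad.Tensor):
        return 1.5 + 0.5 * ad.sin(eta)
    return 1.5 + 0.5 * np.sin(eta)


@dataclass
class LayerSpec:
    """One hidden unit: kind 'mult' or 'div', rows (eta, xi) of W and b."""

    kind: str
    W: np.ndarray
    b: np.ndarray
    W_mask: np.ndarray  # True where trainable; masked entries stay 0
    b_mask: np.ndarray

    def __post_init__(self):
        if self.kind not in ("mult", "div"):
            raise ValueError("layer kind must be 'mult' or 'div'")
        self.W = np.asarray(self.W, dtype=object if _has_exact(self.W) else float)
        self.b = np.asarray(self.b, dtype=object if _has_exact(self.b) else float)
        self.W_mask = np.asarray(self.W_mask, dtype=bool)
        self.b_mask = np.asarray(self.b_mask, dtype=bool)


def _has_exact(a) -> bool:
    return any(
        isinstance(x, (Fraction, sp.Basic)) for x in np.asarray(a, dtype=object).ravel()
    )


@dataclass
class SymNetParameters:
    """Layer weights, read-out, optional power parameter, and masks."""

    channels: list
    layers: list
    w_out: np.ndarray
    b_out: object
    w_out_mask: np.ndarray | None = None
    b_out_mask: bool = True
    eta: float | None = None  # power parameter; alpha = 1.5 + 0.5 sin(eta)
    name: str = ""

    def __post_init__(self):
        self.w_out = np.asarray(
            self.w_out, dtype=object if _has_exact(self.w_out) else float
        )
        if self.w_out_mask is None:
            self.w_out_mask = np.ones(self.w_out.shape, dtype=bool)
        width = len(self.channels)
        for k, layer in enumerate(self.layers):
            if layer.W.shape != (2, width + k):
                raise ValueError(
                    f"layer {k} width {layer.W.shape} != (2, {width + k})"
                )
        if self.w_out.shape != (width + len(self.layers),):
            raise ValueError("read-out width mismatch")

    @property
    def alpha(self):
        return None if self.eta is None else float(alpha_from_eta(self.eta))


def _dot(weights, mask, values, bias):
    """Affine combination generic over value/weight types; skips dead terms."""
    out = bias
    for w, m, x in zip(weights, mask, values):
        if not m and _is_zero_number(w):
            continue
        out = w * x + out
    return out


def _is_zero_number(w) -> bool:
    return not isinstance(w, (ad.Tensor, sp.Basic)) and float(w) == 0.0


def _divide(num, den, penalties, div_registry=None):
    if isinstance(num, ad.Tensor) or isinstance(den, ad.Tensor):
        if penalties is not None:
            gap = ad.relu(DIV_PENALTY_FLOOR - ad.absolute(den))
            n = max(gap.value.size, 1)
            penalties.append(ad.total_sum(gap) * (1.0 / (n * DIV_PENALTY_FLOOR)))
        return ad.safe_div(num, den, DIV_EPS)
    if isinstance(num, sp.Basic) or isinstance(den, sp.Basic):
        if div_registry is not None:
            # keep the denominator opaque so polynomial expansion cannot
            # cancel through it; substituted back during read-out
            inv = sp.Symbol(f"_deninv{len(div_registry)}")
            div_registry[inv] = sp.expand(den)
            return num * inv
        return num / den
    d = np.asarray(den, dtype=float)
    s = np.where(np.sign(d) == 0, 1.0, np.sign(d))
    return num / (s * np.maximum(np.abs(d), DIV_EPS))


def symnet_forward(params: SymNetParameters, lib_values, penalties=None,
                   div_registry=None):
    """Evaluate the network on library channel values.

    ``lib_values`` is a sequence aligned with ``params.channels``.  Values
    may be numpy arrays, autodiff tensors, or sympy expressions; division is
    guarded for the numeric backends (and, when ``penalties`` is a list,
    near-zero denominators contribute an additive penalty term).
    """
    if len(lib_values) != len(params.channels):
        raise ValueError("channel count mismatch")
    L = list(lib_values)
    for layer in params.layers:
        eta_i = _dot(layer.W[0], layer.W_mask[0], L, layer.b[0])
        xi_i = _dot(layer.W[1], layer.W_mask[1], L, layer.b[1])
        if layer.kind == "mult":
            L.append(eta_i * xi_i)
        else:
            L.append(_divide(eta_i, xi_i, penalties, div_registry))
    return _dot(params.w_out, params.w_out_mask, L, params.b_out)


# ---------------------------------------------------------------------------
# parameter packing (only unmasked entries are trainable)
# ---------------------------------------------------------------------------


def _param_slots(params: SymNetParameters):
    for layer in params.layers:
        for r in range(2):
            for c in np.flatnonzero(layer.W_mask[r]):
                yield ("W", layer, r, int(c))
            if layer.b_mask[r]:
                yield ("b", layer, r, None)
    for c in np.flatnonzero(params.w_out_mask):
        yield ("wout", params, int(c), None)
    if params.b_out_mask:
        yield ("bout", params, None, None)


def count_parameters(params) -> int:
    """Number of trainable entries in W, b and the power parameter.

    Accepts a single network or an iterable of networks (a coupled system);
    the power parameter is counted once per network that has one.
    """
    if isinstance(params, SymNetParameters):
        params = [params]
    total = 0
    for p in params:
        total += sum(1 for _ in _param_slots(p))
        if p.eta is not None:
            total += 1
    return total


def pack_parameters(params: SymNetParameters, include_eta=True) -> np.ndarray:
    vals = []
    for slot in _param_slots(params):
        kind, obj, a, b = slot
        if kind == "W":
            vals.append(float(obj.W[a, b]))
        elif kind == "b":
            vals.append(float(obj.b[a]))
        elif kind == "wout":
            vals.append(float(obj.w_out[a]))
        else:
            vals.append(float(obj.b_out))
    if include_eta and params.eta is not None:
        vals.append(float(params.eta))
    return np.array(vals)


def unpack_parameters(params: SymNetParameters, vec, include_eta=True) -> None:
    """Write a flat value vector (floats or tensors) back into the slots."""
    vec = list(vec)
    n_slots = sum(1 for _ in _param_slots(params))
    want = n_slots + (1 if include_eta and params.eta is not None else 0)
    if len(vec) != want:
        raise ValueError(f"expected {want} parameters, got {len(vec)}")
    tensorish = any(isinstance(x, ad.Tensor) for x in vec)
    if tensorish:
        for layer in params.layers:
            layer.W = np.asarray(layer.W, dtype=object)
            layer.b = np.asarray(layer.b, dtype=object)
        params.w_out = np.asarray(params.w_out, dtype=object)
    for slot, val in zip(_param_slots(params), vec):
        kind, obj, a, b = slot
        if kind == "W":
            obj.W[a, b] = val
        elif kind == "b":
            obj.b[a] = val
        elif kind == "wout":
            obj.w_out[a] = val
        else:
            obj.b_out = val
    if include_eta and params.eta is not None:
        params.eta = vec[n_slots]


# ---------------------------------------------------------------------------
# exact symbolic read-out
# ---------------------------------------------------------------------------


@dataclass
class SymbolicTerm:
    """One additive term: ``coeff * num`` or ``num / den`` (coeff folded in).

    kinds: 'mono' (polynomial monomial), 'diffusion' (second-derivative
    channel), 'derivative' (first-derivative channel), 'power' (u^alpha),
    'integral-product' (monomial times the integral channel), 'rational'
    (numerator polynomial over a denominator polynomial, coefficients kept
    inside ``num``).
    """

    kind: str
    num: sp.Expr
    den: sp.Expr | None = None
    coeff: object = 1

    def as_sympy(self) -> sp.Expr:
        e = self.coeff * self.num
        return e / self.den if self.den is not None else e

    def __str__(self):
        return sp.sstr(self.as_sympy())


@dataclass
class SymbolicModel:
    """Flat expression: list of terms with an evaluation helper."""

    terms: list
    alpha: float | None = None

    def as_sympy(self) -> sp.Expr:
        return sp.Add(*[t.as_sympy() for t in self.terms])

    def free_symbols(self):
        return sorted(self.as_sympy().free_symbols, key=lambda s: s.name)

    def lambdify(self):
        syms = self.free_symbols()
        f = sp.lambdify(syms, self.as_sympy(), modules="numpy")
        names = [s.name for s in syms]

        def ev(env: dict):
            return f(*[env[n] for n in names])

        return ev

    def coefficient(self, expr) -> object:
        """Collected coefficient of a monomial among the non-rational terms."""
        target = sp.sympify(expr)
        poly = sp.expand(
            sp.Add(*[t.coeff * t.num for t in self.terms if t.den is None])
        )
        gens = sorted(poly.free_symbols | target.free_symbols, key=lambda s: s.name)
        if not gens:
            return poly
        p = sp.Poly(poly, *gens)
        if target.is_Number:
            return p.coeff_monomial(sp.Integer(1))
        return p.coeff_monomial(target)

    def __str__(self):
        return " + ".join(str(t) for t in self.terms) if self.terms else "0"


_DERIV1 = {"u_x", "v_x"}
_DERIV2 = {"u_xx", "u_yy", "v_xx", "v_yy"}


def _classify(num: sp.Expr, den) -> str:
    names = {s.name for s in num.free_symbols}
    if den is not None:
        return "rational"
    if names & _DERIV2:
        return "diffusion"
    if names & _DERIV1:
        return "derivative"
    if "u_alpha" in names and "I_int" in names:
        return "integral-product"
    if "u_alpha" in names:
        return "power"
    if "I_int" in names:
        return "integral-product"
    return "mono"


def symnet_to_expression(
    params: SymNetParameters, prune_tol: float = 1e-4, exact: bool = False
) -> SymbolicModel:
    """Exact symbolic expansion of the network.

    Multiplication units are expanded into monomials and like terms are
    collected; division units stay as rational terms grouped by their
    denominator polynomial.  Terms whose coefficient magnitude falls below
    ``prune_tol`` are dropped (display-level pruning only; real
    sparsification happens downstream).  With ``exact=True`` float weights
    are converted to exact rationals via their decimal representation.
    """
    syms = [CHANNEL_SYMBOLS[c] for c in params.channels]
    p = params
    if exact:
        p = _exact_copy(params)
    registry: dict[sp.Symbol, sp.Expr] = {}
    out = symnet_forward(p, syms, div_registry=registry)
    expr = sp.expand(sp.sympify(out))

    groups: dict[sp.Expr, sp.Expr] = {}
    for term in sp.Add.make_args(expr):
        den = sp.Integer(1)
        num_factors = []
        for base, power in term.as_powers_dict().items():
            if base in registry:
                den = den * registry[base] ** power
            else:
                num_factors.append(base**power)
        den = sp.expand(den)
        groups[den] = groups.get(den, sp.Integer(0)) + sp.Mul(*num_factors)

    terms: list[SymbolicTerm] = []
    for den, num in groups.items():
        num = sp.expand(num)
        if den == 1:
            for mono in sp.Add.make_args(num):
                coeff, rest = mono.as_coeff_Mul()
                if abs(float(coeff)) < prune_tol:
                    continue
                terms.append(
                    SymbolicTerm(_classify(rest, None), rest, None, coeff)
                )
        else:
            scale = max(
                (abs(float(m.as_coeff_Mul()[0])) for m in sp.Add.make_args(num)),
                default=0.0,
            )
            if scale < prune_tol:
                continue
            terms.append(SymbolicTerm("rational", num, den, 1))
    alpha = p.alpha if p.eta is not None else None
    return SymbolicModel(terms, alpha)


def _to_exact(x):
    if isinstance(x, (sp.Basic, Fraction)):
        return sp.nsimplify(x, rational=True)
    return sp.Rational(str(float(x)))


def _exact_copy(params: SymNetParameters) -> SymNetParameters:
    layers = []
    for layer in params.layers:
        layers.append(
            LayerSpec(
                layer.kind,
                np.array(
                    [[_to_exact(w) for w in row] for row in layer.W], dtype=object
                ),
                np.array([_to_exact(b) for b in layer.b], dtype=object),
                layer.W_mask.copy(),
                layer.b_mask.copy(),
            )
        )
    return SymNetParameters(
        list(params.channels),
        layers,
        np.array([_to_exact(w) for w in params.w_out], dtype=object),
        _to_exact(params.b_out),
        params.w_out_mask.copy(),
        params.b_out_mask,
        params.eta,
        params.name,
    )


# ---------------------------------------------------------------------------
# architectures
# ---------------------------------------------------------------------------


def _full_layer(kind: str, width: int) -> LayerSpec:
    return LayerSpec(
        kind,
        np.zeros((2, width)),
        np.zeros(2),
        np.ones((2, width), dtype=bool),
        np.ones(2, dtype=bool),
    )


def _masked_layer(kind: str, width: int, rows: list[dict], biases=(False, False)):
    """rows: per row a dict {channel_index: initial_weight}; only those
    entries are trainable."""
    W = np.zeros((2, width))
    Wm = np.zeros((2, width), dtype=bool)
    b = np.zeros(2)
    bm = np.array(biases, dtype=bool)
    for r, row in enumerate(rows):
        for c, w0 in row.items():
            W[r, c] = w0
            Wm[r, c] = True
    return LayerSpec(kind, W, b, Wm, bm)


def generic_symnet(
    channels=None, kinds=("mult", "div", "div", "mult", "mult"), eta=None
) -> SymNetParameters:
    """The fully connected demo network: all weights trainable."""
    channels = channels or [
        "u", "ux", "uxx", "v", "vx", "vxx", "u2", "v2", "ualpha", "I",
    ]
    n = len(channels)
    layers = [_full_layer(k, n + i) for i, k in enumerate(kinds)]
    return SymNetParameters(
        channels,
        layers,
        np.zeros(n + len(kinds)),
        0.0,
        eta=eta,
        name="generic",
    )


def worked_example_params() -> SymNetParameters:
    """The published five-hidden-layer instantiation used as an exactness
    oracle: units [mult, div, div, mult, mult] over the ten-channel demo
    library, with the printed layer weights and biases."""
    p = generic_symnet()

    def e(i, width):  # 1-based unit row vector
        row = np.zeros(width)
        row[i - 1] = 1.0
        return row

    W = [layer.W for layer in p.layers]
    b = [layer.b for layer in p.layers]
    W[0][0] = e(1, 10) + e(4, 10)
    W[0][1] = e(1, 10) + e(4, 10)
    b[0][:] = (1.0, 0.0)
    W[1][0] = e(4, 11)
    W[1][1] = 4 * e(4, 11) + e(8, 11)
    b[1][:] = (0.5, 0.5)
    W[2][0] = 0.5 * e(1, 12)
    W[2][1] = 0.2 * e(1, 12) + e(7, 12)
    b[2][:] = (1.0, 0.0)
    W[3][0] = 0.2 * e(1, 13)
    W[3][1] = e(12, 13)
    W[4][0] = 0.2 * e(4, 14)
    W[4][1] = e(13, 14)
    p.w_out = 0.1 * e(1, 15) + 0.3 * e(3, 15) + 6 * e(4, 15) + e(11, 15) \
        + 2 * e(14, 15) + 3 * e(15, 15)
    p.b_out = 0.0
    return p


EX1_CHANNELS = ["u", "uxx", "uyy", "v", "vxx", "vyy"]
EX2_F1_CHANNELS = ["u", "ux", "uxx", "v", "vx", "vxx", "I", "ualpha"]
EX2_F2_CHANNELS = ["u", "ux", "uxx", "v", "vx", "vxx"]


def example1_symnet(name: str = "F1", rng=None,
                    baseline: bool = False) -> SymNetParameters:
    """2-D benchmark wiring: quadratic polynomial part plus one rational
    interaction with a u-quadratic denominator.

    Hidden units (channel indices 6..9 as appended):
      f1 = (a u + b v + c)(d u + e v + g)   general quadratic
      f2 = (a u + b)(c v + d)               u-v cross factor
      f3 = (a u + b)(c u + d)               denominator quadratic in u
      f4 = (w f2 + b) / (w' f3)             rational term
    Read-out over all channels; 28 trainable weights/biases per equation.
    """
    n = len(EX1_CHANNELS)
    iu, iv = 0, 3
    if baseline:
        # polynomial-only library: quadratic unit plus linear read-out
        layers = [
            _masked_layer(
                "mult", n, [{iu: 0.0, iv: 0.0}, {iu: 0.0, iv: 0.0}],
                (True, True),
            ),
        ]
        p = SymNetParameters(
            EX1_CHANNELS, layers, np.zeros(n + 1), 0.0, name=name
        )
        if rng is not None:
            _random_init(p, rng)
        return p
    layers = [
        _masked_layer(
            "mult", n, [{iu: 0.0, iv: 0.0}, {iu: 0.0, iv: 0.0}], (True, True)
        ),
        _masked_layer("mult", n + 1, [{iu: 0.0}, {iv: 0.0}], (True, True)),
        _masked_layer("mult", n + 2, [{iu: 0.0}, {iu: 0.0}], (True, True)),
        # denominator = w*f3 + b: with the additive bias the quadratic can
        # be positive definite (irreducible), which factored forms cannot
        _masked_layer("div", n + 3, [{n + 1: 0.0}, {n + 2: 0.0}], (False, True)),
    ]
    p = SymNetParameters(
        EX1_CHANNELS, layers, np.zeros(n + 4), 0.0, name=name
    )
    layers[3].b[1] = 1.0  # denominator starts away from the guarded region
    if rng is not None:
        _random_init(p, rng)
        # factor units start at their natural O(1) scale so the rational
        # unit's denominator begins well away from the guarded region
        layers[1].W[0, iu] += 1.0
        layers[1].W[1, iv] += 1.0
        layers[2].W[0, iu] += 1.0
        layers[2].W[1, iu] += 1.0
        layers[3].W[1, n + 2] += 1.0
    return p


def example2_symnet_f1(rng=None, den_const_init: float = 0.05) -> SymNetParameters:
    """1-D benchmark wiring for the nonlinear equation.

    Hidden units (appended as channels 8..10):
      f1 = (w u^alpha + b)(w' I)            nonlocal power product
      f2 = (a v + b)(c v + d)               denominator quadratic in v
      f3 = (w u) / (w' f2 + b')             rational calcium feedback
    Read-out over all channels except the bare denominator factor f2 (the
    a-priori constraint: nonlinear v-dependence only through the fraction);
    21 weights/biases plus the power parameter.
    """
    n = len(EX2_F1_CHANNELS)
    ii, ia, iv, iu = 6, 7, 3, 0
    layers = [
        _masked_layer("mult", n, [{ia: 0.0}, {ii: 0.0}], (True, False)),
        _masked_layer("mult", n + 1, [{iv: 0.0}, {iv: 0.0}], (True, True)),
        _masked_layer("div", n + 2, [{iu: 0.0}, {n + 1: 0.0}], (False, True)),
    ]
    w_out_mask = np.ones(n + 3, dtype=bool)
    w_out_mask[n + 1] = False  # f2 itself never appears in the output
    p = SymNetParameters(
        EX2_F1_CHANNELS, layers, np.zeros(n + 3), 0.0,
        w_out_mask=w_out_mask, eta=0.0, name="F1"
    )
    # denominator constant starts at the squared scale of the calcium field
    # so the fraction's curvature in v is visible to the gradient
    layers[2].b[1] = den_const_init
    if rng is not None:
        _random_init(p, rng)
        layers[0].W[0, ia] += 1.0
        layers[0].W[1, ii] += 1.0
        layers[1].W[0, iv] += 1.0
        layers[1].W[1, iv] += 1.0
        layers[2].W[1, n + 1] += 1.0
        layers[2].b[1] = den_const_init
    return p


def example2_symnet_f2(rng=None) -> SymNetParameters:
    """Linear read-out for the second (linear) equation: 7 parameters."""
    p = SymNetParameters(
        EX2_F2_CHANNELS, [], np.zeros(6), 0.0, name="F2"
    )
    if rng is not None:
        _random_init(p, rng)
    return p


def example2_symnet_baseline(rng=None, name: str = "F1") -> SymNetParameters:
    """Polynomial-only 1-D baseline: quadratic unit + linear read-out."""
    n = len(EX2_F2_CHANNELS)
    iu, iv = 0, 3
    layers = [
        _masked_layer(
            "mult", n, [{iu: 0.0, iv: 0.0}, {iu: 0.0, iv: 0.0}], (True, True)
        ),
    ]
    p = SymNetParameters(
        EX2_F2_CHANNELS, layers, np.zeros(n + 1), 0.0, name=name
    )
    if rng is not None:
        _random_init(p, rng)
    return p


def _random_init(params: SymNetParameters, rng, scale: float = 0.1) -> None:
    """N(0, scale^2) on trainable entries; division denominators get a unit
    bias so the guarded region is avoided at the start."""
    vec = rng.normal(0.0, scale, size=len(pack_parameters(params, False)))
    unpack_parameters(params, vec, include_eta=False)
    if params.eta is not None:
        params.eta = 0.0
    for layer in params.layers:
        if layer.kind == "div" and layer.b_mask[1]:
            layer.b[1] = 1.0
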