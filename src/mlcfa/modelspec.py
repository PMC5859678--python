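"""Factor-pattern specification, model kinds, parameter and df counting.

Five model kinds are distinguished:

``CFA``
    A conventional one-level factor model fitted to the total sample
    covariance S_T, ignoring clustering.
``MCFA``
    A two-level model with hypothesised factor structures at both the
    within (pooled S_PW) and between (scaled S_B) level.
``MAX_MCFA``
    The "maximum" model: hypothesised within structure, fully saturated
    between level. The saturated block consumes exactly its own moments,
    so misfit is attributable to the within-level model alone.
``PS_BETWEEN``
    Partially saturated the other way round: saturated within level,
    hypothesised between level; isolates between-level misfit.
``SATURATED`` / ``INDEPENDENCE``
    Degenerate kinds used as exact-fit and CFI-baseline references.

Latent scales are set with marker variables: by default the first listed
indicator of each factor has its loading fixed (at 1.0 unless overridden).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .exceptions import ConfigurationError, UnidentifiableModelError

FREE = "free"
ZERO = "zero"


class ModelKind(str, Enum):
    CFA = "CFA"
    MCFA = "MCFA"
    MAX_MCFA = "MAX_MCFA"
    PS_BETWEEN = "PS_BETWEEN"
    SATURATED = "SATURATED"
    INDEPENDENCE = "INDEPENDENCE"


#: tokens usable in place of a FactorPattern for one level
SATURATED_LEVEL = "saturated"
INDEPENDENCE_LEVEL = "independence"

TWO_LEVEL_KINDS = {ModelKind.MCFA, ModelKind.MAX_MCFA, ModelKind.PS_BETWEEN}


@dataclass(frozen=True)
class FactorPattern:
    """Loading pattern, factor-covariance spec and residual spec for one level.

    ``loadings[j][r]`` is ``"free"``, ``"zero"`` or a fixed numeric value.
    The factor covariance Psi is symmetric with free diagonal; off-diagonals
    are free by default (``correlated=True``). Residual variances Theta are
    a free diagonal.
    """

    indicators: tuple[str, ...]
    factors: tuple[str, ...]
    loadings: tuple[tuple[object, ...], ...]
    correlated: bool = True

    def __post_init__(self):
        p, m = len(self.indicators), len(self.factors)
        if len(self.loadings) != p or any(len(row) != m for row in self.loadings):
            raise ConfigurationError("loading pattern must be p x m")
        for r in range(m):
            col = [row[r] for row in self.loadings]
            nonzero = [e for e in col if e != ZERO]
            if not nonzero:
                raise ConfigurationError(
                    f"factor {self.factors[r]!r} has no nonzero loading"
                )
            fixed = [e for e in nonzero if not isinstance(e, str)]
            if len(fixed) == 0:
                raise ConfigurationError(
                    f"factor {self.factors[r]!r} has no fixed marker loading"
                )

    @property
    def p(self) -> int:
        return len(self.indicators)

    @property
    def m(self) -> int:
        return len(self.factors)

    def n_free_loadings(self) -> int:
        return sum(e == FREE for row in self.loadings for e in row)

    def n_free(self) -> int:
        m = self.m
        psi = m * (m + 1) // 2 if self.correlated else m
        return self.n_free_loadings() + psi + self.p


def pattern_from_dict(
    spec: dict[str, list[str]],
    indicators: list[str] | tuple[str, ...],
    marker_value: float = 1.0,
    correlated: bool = True,
) -> FactorPattern:
    """Build a simple-structure pattern from ``{factor: [indicators...]}``.

    The first indicator listed for each factor becomes its marker, with the
    loading fixed at ``marker_value``.
    """
    indicators = tuple(indicators)
    factors = tuple(spec.keys())
    for f, items in spec.items():
        unknown = [v for v in items if v not in indicators]
        if unknown:
            raise ConfigurationError(
                f"factor {f!r} references unknown indicator(s) {unknown}; "
                f"known: {list(indicators)}"
            )
        if not items:
            raise ConfigurationError(f"factor {f!r} lists no indicators")
    rows = []
    for ind in indicators:
        row = []
        for f, items in spec.items():
            if ind not in items:
                row.append(ZERO)
            elif ind == items[0]:
                row.append(float(marker_value))
            else:
                row.append(FREE)
        rows.append(tuple(row))
    return FactorPattern(indicators, factors, tuple(rows), correlated)


@dataclass(frozen=True)
class ModelDefinition:
    """A model kind plus per-level structure sharing one indicator order."""

    kind: ModelKind
    indicators: tuple[str, ...]
    within: FactorPattern | str | None = None
    between: FactorPattern | str | None = None
    meta: dict = field(default_factory=dict, compare=False)

    @property
    def p(self) -> int:
        return len(self.indicators)

    def moment_count(self) -> int:
        pp = self.p * (self.p + 1) // 2
        return 2 * pp if self.kind in TWO_LEVEL_KINDS else pp

    def level_free(self, level: str) -> int:
        """Free-parameter count of one level block."""
        struct = self.within if level == "within" else self.between
        pp = self.p * (self.p + 1) // 2
        if struct is None:
            return 0
        if struct == SATURATED_LEVEL:
            return pp
        if struct == INDEPENDENCE_LEVEL:
            return self.p
        return struct.n_free()

    def free_parameter_count(self) -> int:
        if self.kind in TWO_LEVEL_KINDS:
            return self.level_free("within") + self.level_free("between")
        return self.level_free("within")


def build_model(
    kind: ModelKind | str,
    within_spec: FactorPattern | str | None = None,
    between_spec: FactorPattern | str | None = None,
) -> ModelDefinition:
    """Assemble and validate a :class:`ModelDefinition`.

    ``CFA`` uses ``within_spec`` only (fitted to S_T); ``MAX_MCFA`` pairs it
    with a saturated between level; ``MCFA`` pairs both specs; ``PS_BETWEEN``
    pairs a saturated within level with ``between_spec``.
    """
    kind = ModelKind(kind)

    def _indicators(s):
        return s.indicators if isinstance(s, FactorPattern) else None

    if kind is ModelKind.CFA:
        if not isinstance(within_spec, FactorPattern):
            raise ConfigurationError("CFA requires a within factor pattern")
        model = ModelDefinition(kind, within_spec.indicators, within=within_spec)
    elif kind is ModelKind.MAX_MCFA:
        if not isinstance(within_spec, FactorPattern):
            raise ConfigurationError("MAX_MCFA requires a within factor pattern")
        model = ModelDefinition(
            kind, within_spec.indicators, within=within_spec, between=SATURATED_LEVEL
        )
    elif kind is ModelKind.MCFA:
        if not isinstance(within_spec, FactorPattern) or not isinstance(
            between_spec, FactorPattern
        ):
            raise ConfigurationError("MCFA requires within and between patterns")
        if within_spec.indicators != between_spec.indicators:
            raise ConfigurationError(
                "between/within indicator order mismatch: "
                f"within={list(within_spec.indicators)} "
                f"between={list(between_spec.indicators)}"
            )
        model = ModelDefinition(
            kind, within_spec.indicators, within=within_spec, between=between_spec
        )
    elif kind is ModelKind.PS_BETWEEN:
        if not isinstance(between_spec, FactorPattern):
            raise ConfigurationError("PS_BETWEEN requires a between factor pattern")
        model = ModelDefinition(
            kind, between_spec.indicators, within=SATURATED_LEVEL, between=between_spec
        )
    elif kind is ModelKind.SATURATED:
        ind = _indicators(within_spec) or _indicators(between_spec)
        if ind is None:
            raise ConfigurationError(
                "SATURATED needs a pattern (or indicator list) to take labels from"
            )
        model = ModelDefinition(
            kind, ind, within=SATURATED_LEVEL, between=None
        )
    elif kind is ModelKind.INDEPENDENCE:
        ind = _indicators(within_spec) or _indicators(between_spec)
        if ind is None:
            raise ConfigurationError("INDEPENDENCE needs indicator labels")
        model = ModelDefinition(kind, ind, within=INDEPENDENCE_LEVEL, between=None)
    else:  # pragma: no cover
        raise ConfigurationError(f"unknown model kind {kind}")

    if model.free_parameter_count() > model.moment_count():
        raise UnidentifiableModelError(
            f"{kind.value}: {model.free_parameter_count()} free parameters exceed "
            f"{model.moment_count()} fitted moments"
        )
    return model


def degrees_of_freedom(model: ModelDefinition, scope: str = "overall") -> int:
    """Degrees of freedom, overall or level-specific.

    ``within_specific`` df equals the df of the maximum model built from the
    model's within pattern (the saturated between block consumes its own
    moments); ``between_specific`` df equals between moments minus between
    free parameters, i.e. the df of the partially saturated between model.
    """
    pp = model.p * (model.p + 1) // 2
    if scope == "overall":
        df = model.moment_count() - model.free_parameter_count()
    elif scope == "within_specific":
        if model.within in (None, SATURATED_LEVEL):
            raise ConfigurationError("no hypothesised within structure")
        df = pp - model.level_free("within")
    elif scope == "between_specific":
        if model.between in (None, SATURATED_LEVEL):
            raise ConfigurationError("no hypothesised between structure")
        df = pp - model.level_free("between")
    else:
        raise ConfigurationError(f"unknown scope {scope!r}")
    if df < 0:
        raise UnidentifiableModelError(f"negative degrees of freedom ({df})")
    return df
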