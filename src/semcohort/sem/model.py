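"""Declarative covariance-structure model descriptions.

A model is written one statement per line::

    factor Inflammation: tnfr1 tnfr2 opg opn
    factor Myocardium: ntprobnp fix_error=0
    second_order InflOx: Inflammation OxStress
    observed_exogenous sel_age
    path sel_age -> InflOx
    # comments start with '#'

Identification is applied at parse time: under the ``marker-variable``
rule the first indicator loading of every factor (and the first
second-order loading) is fixed to 1; under ``unit-latent-variance`` all
loadings are free and every latent (co)variance diagonal entry is fixed
to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ..errors import ModelSpecError

IDENTIFICATION_RULES = ("marker-variable", "unit-latent-variance")


@dataclass(frozen=True)
class ModelSpec:
    """Validated structural description of a covariance-structure model.

    Latents are ordered: first-order factors (in order of appearance),
    then the optional second-order factor, then one pseudo-latent per
    observed exogenous variable (loading 1, error 0).
    """

    manifest_names: tuple[str, ...]
    factors: tuple[tuple[str, tuple[str, ...]], ...]
    second_order: tuple[str, tuple[str, ...]] | None
    observed_exogenous: tuple[str, ...]
    paths: tuple[tuple[str, str], ...]  # (source, target)
    fixed_error: dict[str, float] = field(default_factory=dict)
    identification: str = "marker-variable"

    @property
    def latent_names(self) -> tuple[str, ...]:
        names = [f for f, _ in self.factors]
        if self.second_order is not None:
            names.append(self.second_order[0])
        names.extend(self.observed_exogenous)
        return tuple(names)

    @property
    def first_order_names(self) -> tuple[str, ...]:
        return tuple(f for f, _ in self.factors)

    @property
    def n_manifest(self) -> int:
        return len(self.manifest_names)

    @property
    def n_latent(self) -> int:
        return len(self.latent_names)

    def indicators_of(self, factor: str) -> tuple[str, ...]:
        for name, inds in self.factors:
            if name == factor:
                return inds
        if factor in self.observed_exogenous:
            return (factor,)
        raise KeyError(factor)

    @property
    def edges(self) -> tuple[tuple[str, str], ...]:
        """All directed latent-level edges (source, target), structural
        paths plus second-order loadings."""
        out = list(self.paths)
        if self.second_order is not None:
            name, governed = self.second_order
            out.extend((name, g) for g in governed)
        return tuple(out)

    @property
    def endogenous_latents(self) -> tuple[str, ...]:
        targets = {t for _, t in self.edges}
        return tuple(name for name in self.latent_names if name in targets)

    @property
    def exogenous_latents(self) -> tuple[str, ...]:
        targets = {t for _, t in self.edges}
        return tuple(name for name in self.latent_names if name not in targets)


def _fail(lineno: int, line: str, msg: str) -> None:
    raise ModelSpecError(f"line {lineno}: {msg!s} [{line.strip()!r}]")


def parse_model(text: str, identification: str = "marker-variable") -> ModelSpec:
    """Parse a model description into a validated :class:`ModelSpec`.

    Raises :class:`ModelSpecError` naming the offending line for unknown
    or duplicate indicators, cyclic paths, or missing scale constraints.
    """
    if identification not in IDENTIFICATION_RULES:
        raise ModelSpecError(
            f"unknown identification rule {identification!r}; "
            f"choose one of {IDENTIFICATION_RULES}"
        )

    factors: list[tuple[str, tuple[str, ...]]] = []
    second_order: tuple[str, tuple[str, ...]] | None = None
    observed_exo: list[str] = []
    paths: list[tuple[str, str]] = []
    fixed_error: dict[str, float] = {}

    manifest: list[str] = []
    seen_indicators: set[str] = set()
    factor_names: set[str] = set()

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = line.split()
        kw = tokens[0]

        if kw == "factor":
            head, sep, rest = line[len("factor"):].partition(":")
            if not sep:
                _fail(lineno, raw, "expected 'factor <Name>: <indicators>'")
            name = head.strip()
            if not name or len(name.split()) != 1:
                _fail(lineno, raw, "factor needs exactly one name")
            if name in factor_names:
                _fail(lineno, raw, f"factor {name!r} declared twice")
            items = rest.split()
            inds: list[str] = []
            fix_val: float | None = None
            for item in items:
                if item.startswith("fix_error="):
                    try:
                        fix_val = float(item.split("=", 1)[1])
                    except ValueError:
                        _fail(lineno, raw, f"bad fix_error value in {item!r}")
                else:
                    inds.append(item)
            if not inds:
                _fail(lineno, raw, f"factor {name!r} has no indicators")
            for ind in inds:
                if ind in seen_indicators:
                    _fail(lineno, raw,
                          f"indicator {ind!r} assigned to two factors")
                seen_indicators.add(ind)
                manifest.append(ind)
            if fix_val is not None:
                for ind in inds:
                    fixed_error[ind] = fix_val
            if len(inds) == 1 and fix_val is None:
                _fail(lineno, raw,
                      f"single-indicator factor {name!r} needs an explicit "
                      "fix_error=<value>")
            factor_names.add(name)
            factors.append((name, tuple(inds)))

        elif kw == "second_order":
            head, sep, rest = line[len("second_order"):].partition(":")
            if not sep:
                _fail(lineno, raw, "expected 'second_order <Name>: <factors>'")
            if second_order is not None:
                _fail(lineno, raw, "only one second_order statement allowed")
            name = head.strip()
            governed = tuple(rest.split())
            if len(governed) < 2:
                _fail(lineno, raw, "second_order needs at least two factors")
            second_order = (name, governed)

        elif kw == "observed_exogenous":
            if len(tokens) != 2:
                _fail(lineno, raw, "expected 'observed_exogenous <name>'")
            name = tokens[1]
            if name in seen_indicators or name in observed_exo:
                _fail(lineno, raw, f"variable {name!r} declared twice")
            observed_exo.append(name)
            manifest.append(name)
            seen_indicators.add(name)

        elif kw == "path":
            if len(tokens) != 4 or tokens[2] != "->":
                _fail(lineno, raw, "expected 'path <A> -> <B>'")
            paths.append((tokens[1], tokens[3]))

        else:
            _fail(lineno, raw, f"unknown statement {kw!r}")

    if not factors and not observed_exo:
        raise ModelSpecError("empty model: no factors or observed variables")

    latent_names = [f for f, _ in factors]
    if second_order is not None:
        so_name, governed = second_order
        if so_name in latent_names or so_name in seen_indicators:
            raise ModelSpecError(f"second_order name {so_name!r} already used")
        for g in governed:
            if g not in latent_names:
                raise ModelSpecError(
                    f"second_order governs unknown factor {g!r}")
        latent_names.append(so_name)
    latent_names.extend(observed_exo)

    edge_targets: set[str] = set()
    for src, tgt in paths:
        if src not in latent_names:
            raise ModelSpecError(f"path source {src!r} is not a latent or "
                                 "observed exogenous variable")
        if tgt not in latent_names or tgt in observed_exo:
            raise ModelSpecError(f"path target {tgt!r} is not a latent")
        edge_targets.add(tgt)

    spec = ModelSpec(
        manifest_names=tuple(manifest),
        factors=tuple(factors),
        second_order=second_order,
        observed_exogenous=tuple(observed_exo),
        paths=tuple(paths),
        fixed_error=fixed_error,
        identification=identification,
    )
    _check_acyclic(spec)
    return spec


def _check_acyclic(spec: ModelSpec) -> None:
    adj: dict[str, list[str]] = {name: [] for name in spec.latent_names}
    for src, tgt in spec.edges:
        adj[src].append(tgt)
    WHITE, GREY, BLACK = 0, 1, 2
    state = {name: WHITE for name in adj}

    def visit(node: str, stack: list[str]) -> None:
        state[node] = GREY
        stack.append(node)
        for nxt in adj[node]:
            if state[nxt] == GREY:
                cyc = " -> ".join(stack + [nxt])
                raise ModelSpecError(f"cyclic paths: {cyc}")
            if state[nxt] == WHITE:
                visit(nxt, stack)
        stack.pop()
        state[node] = BLACK

    for name in adj:
        if state[name] == WHITE:
            visit(name, [])
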