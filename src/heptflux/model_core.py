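"""Small constraint-based metabolic network models.

A :class:`MetabolicModel` is the in-memory form of the central-carbon network
used throughout this package: metabolites (internal species balanced at steady
state, external species on the boundary), reactions with signed stoichiometry
and flux bounds in mmol·gDCW⁻¹·h⁻¹ (the biomass reaction in h⁻¹), a designated
biomass reaction and a set of exchange reactions.

Sign conventions
----------------
Negative stoichiometric coefficients denote consumption, positive production.
Exchange reactions are written ``internal <=> external``, so a *negative*
exchange flux is uptake and a *positive* flux is secretion.

Two serializations are supported: a two-table TSV pair (``*.met.tsv`` +
``*.rxn.tsv`` with a textual stoichiometry expression) and an equivalent
single-file JSON. Round-tripping either format is the identity.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "ModelError",
    "ModelFormatError",
    "load_model",
    "write_model",
    "stoichiometric_matrix",
    "validate_model",
    "BUNDLED_MODELS",
]

COFACTOR_ROLES = frozenset(
    {"none", "ATP", "ADP", "NADH", "NAD", "NADPH", "NADP", "FADH2", "FAD", "Pi", "H"}
)

#: name → data-file stem for models shipped with the package
BUNDLED_MODELS = {"ecoli_core_heptanoate": "ecoli_core_heptanoate"}


class ModelError(ValueError):
    """An invalid model (duplicate ids, dangling references, bad bounds)."""


class ModelFormatError(ModelError):
    """A model file that cannot be parsed; message names the offending line."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    external: bool = False
    cofactor_role: str = "none"

    def __post_init__(self) -> None:
        if self.cofactor_role not in COFACTOR_ROLES:
            raise ModelError(
                f"metabolite {self.id!r}: unknown cofactor_role {self.cofactor_role!r}"
            )


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lb: float = 0.0
    ub: float = 1000.0
    subsystem: str = ""

    @property
    def reversible(self) -> bool:
        return self.lb < 0

    def equation(self) -> str:
        """Render the stoichiometry as ``a + 2 b -> c`` (``<=>`` if reversible)."""

        def side(items: list[tuple[str, float]]) -> str:
            terms = []
            for met, coef in items:
                c = abs(coef)
                terms.append(met if c == 1 else f"{c:g} {met}")
            return " + ".join(terms)

        subs = sorted((m, c) for m, c in self.stoichiometry.items() if c < 0)
        prods = sorted((m, c) for m, c in self.stoichiometry.items() if c > 0)
        arrow = "<=>" if self.reversible else "->"
        return f"{side(subs)} {arrow} {side(prods)}".strip()


@dataclass
class MetabolicModel:
    id: str
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    biomass_id: str | None = None
    exchange_ids: list[str] = field(default_factory=list)

    # -- lookups ---------------------------------------------------------
    def metabolite(self, met_id: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == met_id:
                return m
        raise KeyError(met_id)

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)

    @property
    def internal_metabolites(self) -> list[Metabolite]:
        return [m for m in self.metabolites if not m.external]

    def cofactor_metabolite(self, role: str) -> Metabolite | None:
        """The (single) metabolite annotated with *role*, or None."""
        hits = [m for m in self.metabolites if m.cofactor_role == role]
        if len(hits) > 1:
            raise ModelError(f"multiple metabolites annotated with role {role!r}")
        return hits[0] if hits else None

    # -- validation ------------------------------------------------------
    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty iff the model is valid)."""
        problems: list[str] = []
        met_ids = [m.id for m in self.metabolites]
        rxn_ids = [r.id for r in self.reactions]
        for ids, kind in ((met_ids, "metabolite"), (rxn_ids, "reaction")):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    problems.append(f"duplicate {kind} id {i!r}")
                seen.add(i)
        met_set = set(met_ids)
        for r in self.reactions:
            if not r.stoichiometry:
                problems.append(f"reaction {r.id!r} has empty stoichiometry")
            if r.lb > r.ub:
                problems.append(f"reaction {r.id!r} has lb {r.lb} > ub {r.ub}")
            for met in r.stoichiometry:
                if met not in met_set:
                    problems.append(
                        f"reaction {r.id!r} references unknown metabolite {met!r}"
                    )
        rxn_set = set(rxn_ids)
        if self.biomass_id is not None and self.biomass_id not in rxn_set:
            problems.append(f"biomass_id {self.biomass_id!r} does not resolve")
        for ex in self.exchange_ids:
            if ex not in rxn_set:
                problems.append(f"exchange id {ex!r} does not resolve")
        return problems

    def __eq__(self, other: object) -> bool:
        # content equality: the id label (often derived from a filename) is
        # not part of the scientific content being compared
        if not isinstance(other, MetabolicModel):
            return NotImplemented
        a, b = _model_dict(self), _model_dict(other)
        a.pop("id"), b.pop("id")
        return a == b


# ---------------------------------------------------------------------------
# equation parsing / serialization

_TERM_RE = re.compile(r"^(?:(?P<coef>[0-9.eE+-]+)\s+)?(?P<met>\S+)$")


def _parse_equation(eq: str, line_no: int | None = None) -> tuple[dict[str, float], bool]:
    where = f" (line {line_no})" if line_no is not None else ""
    if "<=>" in eq:
        lhs, rhs = eq.split("<=>")
        reversible = True
    elif "->" in eq:
        lhs, rhs = eq.split("->")
        reversible = False
    else:
        raise ModelFormatError(f"equation {eq!r} has no arrow{where}")
    stoich: dict[str, float] = {}
    for side, sign in ((lhs, -1.0), (rhs, 1.0)):
        side = side.strip()
        if not side:
            continue
        for term in side.split(" + "):
            term = term.strip()
            if not term:
                continue
            m = _TERM_RE.match(term)
            if m is None:
                raise ModelFormatError(f"cannot parse term {term!r}{where}")
            coef = float(m.group("coef")) if m.group("coef") else 1.0
            met = m.group("met")
            stoich[met] = stoich.get(met, 0.0) + sign * coef
    return stoich, reversible


def _model_dict(model: MetabolicModel) -> dict:
    return {
        "id": model.id,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "external": m.external,
                "cofactor_role": m.cofactor_role,
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "stoichiometry": dict(sorted(r.stoichiometry.items())),
                "lb": r.lb,
                "ub": r.ub,
                "subsystem": r.subsystem,
            }
            for r in model.reactions
        ],
        "biomass_id": model.biomass_id,
        "exchange_ids": list(model.exchange_ids),
    }


def _model_from_dict(d: dict) -> MetabolicModel:
    model = MetabolicModel(
        id=d.get("id", "model"),
        metabolites=[Metabolite(**m) for m in d["metabolites"]],
        reactions=[
            Reaction(
                id=r["id"],
                stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                lb=float(r["lb"]),
                ub=float(r["ub"]),
                subsystem=r.get("subsystem", ""),
            )
            for r in d["reactions"]
        ],
        biomass_id=d.get("biomass_id"),
        exchange_ids=list(d.get("exchange_ids", [])),
    )
    return model


# ---------------------------------------------------------------------------
# IO


def _tsv_paths(base: Path) -> tuple[Path, Path]:
    s = str(base)
    for suffix in (".met.tsv", ".rxn.tsv", ".tsv"):
        if s.endswith(suffix):
            s = s[: -len(suffix)]
            break
    return Path(s + ".met.tsv"), Path(s + ".rxn.tsv")


def _load_tsv_pair(met_path: Path, rxn_path: Path, model_id: str) -> MetabolicModel:
    for p in (met_path, rxn_path):
        if not p.exists():
            raise FileNotFoundError(f"model file not found: {p}")
        if p.stat().st_size == 0 or not p.read_text().strip():
            raise ModelFormatError(f"{p}: empty model file (line 1)")
    mets = pd.read_csv(met_path, sep="\t", comment="#", dtype=str)
    rxns = pd.read_csv(rxn_path, sep="\t", comment="#", dtype=str)
    required_m = {"id", "name", "external", "cofactor_role"}
    required_r = {"id", "equation", "lb", "ub", "subsystem"}
    if not required_m.issubset(mets.columns):
        raise ModelFormatError(
            f"{met_path}: missing columns {sorted(required_m - set(mets.columns))} (line 1)"
        )
    if not required_r.issubset(rxns.columns):
        raise ModelFormatError(
            f"{rxn_path}: missing columns {sorted(required_r - set(rxns.columns))} (line 1)"
        )
    mets = mets.fillna("")
    rxns = rxns.fillna("")
    metabolites = [
        Metabolite(
            id=row.id,
            name=row.name_,
            external=str(row.external) in ("1", "True", "true"),
            cofactor_role=row.cofactor_role,
        )
        for row in mets.rename(columns={"name": "name_"}).itertuples(index=False)
    ]
    reactions = []
    for i, row in enumerate(rxns.itertuples(index=False)):
        stoich, _ = _parse_equation(row.equation, line_no=i + 2)
        reactions.append(
            Reaction(
                id=row.id,
                stoichiometry=stoich,
                lb=float(row.lb),
                ub=float(row.ub),
                subsystem=row.subsystem if isinstance(row.subsystem, str) else "",
            )
        )
    biomass = [r.id for r in reactions if r.subsystem == "Biomass"]
    exchanges = [r.id for r in reactions if r.subsystem == "Exchange"]
    model = MetabolicModel(
        id=model_id,
        metabolites=metabolites,
        reactions=reactions,
        biomass_id=biomass[0] if biomass else None,
        exchange_ids=exchanges,
    )
    return model


def load_model(source: str | Path) -> MetabolicModel:
    """Load a model from a bundled name, a JSON file, or a TSV-pair base path.

    Raises
    ------
    FileNotFoundError
        If *source* is neither a bundled name nor an existing file.
    ModelFormatError
        On unparseable files (the message names the offending line).
    ModelError
        If the parsed model violates an invariant (the message names it).
    """
    if isinstance(source, str) and source in BUNDLED_MODELS:
        stem = BUNDLED_MODELS[source]
        pkg = resources.files("heptflux") / "data"
        model = _load_tsv_pair(
            Path(str(pkg / f"{stem}.met.tsv")), Path(str(pkg / f"{stem}.rxn.tsv")), source
        )
    else:
        path = Path(source)
        if path.suffix == ".json":
            if not path.exists():
                raise FileNotFoundError(f"model file not found: {path}")
            text = path.read_text()
            if not text.strip():
                raise ModelFormatError(f"{path}: empty model file (line 1)")
            model = _model_from_dict(json.loads(text))
        else:
            met_path, rxn_path = _tsv_paths(path)
            model = _load_tsv_pair(met_path, rxn_path, met_path.stem.replace(".met", ""))
    problems = model.validate()
    if problems:
        raise ModelError("invalid model: " + "; ".join(problems))
    return model


def write_model(model: MetabolicModel, path: str | Path) -> None:
    """Write *model* as JSON (``.json``) or as a TSV pair (any other path)."""
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(_model_dict(model), indent=1) + "\n")
        return
    met_path, rxn_path = _tsv_paths(path)
    with open(met_path, "w") as fh:
        fh.write("id\tname\texternal\tcofactor_role\n")
        for m in model.metabolites:
            fh.write(f"{m.id}\t{m.name}\t{int(m.external)}\t{m.cofactor_role}\n")
    with open(rxn_path, "w") as fh:
        fh.write("id\tequation\tlb\tub\tsubsystem\n")
        for r in model.reactions:
            sub = r.subsystem
            if r.id == model.biomass_id and sub != "Biomass":
                sub = "Biomass"
            if r.id in model.exchange_ids and sub != "Exchange":
                sub = "Exchange"
            fh.write(f"{r.id}\t{r.equation()}\t{r.lb:g}\t{r.ub:g}\t{sub}\n")


def stoichiometric_matrix(model: MetabolicModel) -> pd.DataFrame:
    """Stoichiometric matrix S with internal metabolites as rows, reactions as columns.

    External metabolites are excluded: they carry no steady-state balance.
    Entry (i, j) is the signed coefficient of metabolite i in reaction j,
    exactly as written in the model file (no normalization).
    """
    rows = [m.id for m in model.internal_metabolites]
    cols = [r.id for r in model.reactions]
    S = np.zeros((len(rows), len(cols)))
    row_index = {m: i for i, m in enumerate(rows)}
    for j, r in enumerate(model.reactions):
        for met, coef in r.stoichiometry.items():
            i = row_index.get(met)
            if i is not None:
                S[i, j] = coef
    return pd.DataFrame(S, index=rows, columns=cols)


def validate_model(model: MetabolicModel) -> list[str]:
    """Report-based validation; see :meth:`MetabolicModel.validate`."""
    return model.validate()
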