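"""Stoichiometric network container and the packaged central-carbon fixture.

The canonical format is a tab-separated text file with two record kinds:

    @metabolite <TAB> ID <TAB> long name <TAB> external(0/1)
    reaction_id <TAB> reversible(0/1) <TAB> equation

where equations use ``2 A + B -> C`` syntax (``<->`` marks reversible, and the
flag column must agree).  Lines starting with ``#`` are comments.

The packaged fixture ``data/ar36_synthetic_network.tsv`` is a synthetic
reconstruction of the central carbon metabolism of a PTS-minus,
shikimate-overproducing E. coli strain grown on glucose plus yeast extract:
60 reactions, 44 internal metabolites and 6 external species (GLC, YE, SA,
AC, BIOMASS, MAINT).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicNetwork",
    "load_network",
    "save_network",
    "load_fixture_network",
    "stoichiometric_matrix",
    "ye_decomposition",
    "validate",
    "FIXTURE_NAME",
]

FIXTURE_NAME = "ar36_synthetic_network.tsv"


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    external: bool = False


@dataclass
class Reaction:
    id: str
    stoichiometry: dict  # metabolite id -> signed coefficient
    reversible: bool = False

    def __post_init__(self):
        coeffs = list(self.stoichiometry.values())
        if not coeffs:
            raise ValueError(f"reaction {self.id!r} has empty stoichiometry")
        if any(c == 0 or not np.isfinite(c) for c in coeffs):
            raise ValueError(f"reaction {self.id!r} has zero/non-finite coefficient")
        if not (any(c < 0 for c in coeffs) and any(c > 0 for c in coeffs)):
            raise ValueError(
                f"reaction {self.id!r} needs at least one substrate and one product")

    def equation(self) -> str:
        def side(sign):
            parts = []
            for met, c in self.stoichiometry.items():
                if (c < 0) == (sign < 0) and c != 0:
                    a = abs(c)
                    coef = "" if a == 1 else (f"{a:g} ")
                    parts.append(f"{coef}{met}")
            return " + ".join(parts)
        arrow = "<->" if self.reversible else "->"
        return f"{side(-1)} {arrow} {side(+1)}"


@dataclass
class MetabolicNetwork:
    metabolites: list
    reactions: list

    def __post_init__(self):
        ids = [m.id for m in self.metabolites]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate metabolite ids")
        rids = [r.id for r in self.reactions]
        dup = {x for x in rids if rids.count(x) > 1}
        if dup:
            raise ValueError(f"duplicate reaction id(s): {sorted(dup)}")
        known = set(ids)
        for r in self.reactions:
            unknown = set(r.stoichiometry) - known
            if unknown:
                raise ValueError(
                    f"reaction {r.id!r} references undeclared metabolite(s): "
                    f"{sorted(unknown)}")

    @property
    def internal_metabolites(self):
        return [m for m in self.metabolites if not m.external]

    @property
    def external_metabolites(self):
        return [m for m in self.metabolites if m.external]

    @property
    def reaction_ids(self):
        return [r.id for r in self.reactions]

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)


_TERM_RE = re.compile(r"^\s*(?:(\d+(?:\.\d+)?)\s+)?(\S+)\s*$")


def _parse_side(text: str, sign: int, stoich: dict) -> None:
    for term in text.split("+"):
        term = term.strip()
        if not term:
            continue
        m = _TERM_RE.match(term)
        if not m:
            raise ValueError(f"cannot parse term {term!r}")
        coef = float(m.group(1)) if m.group(1) else 1.0
        met = m.group(2)
        stoich[met] = stoich.get(met, 0.0) + sign * coef
        if stoich[met] == 0:
            del stoich[met]


def parse_equation(eq: str) -> tuple[dict, bool]:
    """Parse ``2 A + B -> C`` / ``A <-> B`` into (stoichiometry, reversible)."""
    if "<->" in eq:
        lhs, rhs = eq.split("<->")
        rev = True
    elif "->" in eq:
        lhs, rhs = eq.split("->")
        rev = False
    else:
        raise ValueError(f"no arrow in equation {eq!r}")
    stoich: dict = {}
    _parse_side(lhs, -1, stoich)
    _parse_side(rhs, +1, stoich)
    return stoich, rev


def load_network(path) -> MetabolicNetwork:
    """Load a network from the TSV dialect; errors carry line numbers."""
    path = Path(path)
    metabolites, reactions = [], []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        try:
            if fields[0] == "@metabolite":
                if len(fields) != 4:
                    raise ValueError("@metabolite needs ID, name, external flag")
                metabolites.append(Metabolite(id=fields[1], name=fields[2],
                                              external=fields[3] == "1"))
            else:
                if len(fields) != 3:
                    raise ValueError("reaction row needs id, reversible, equation")
                rid, rev_flag, eq = fields
                stoich, rev = parse_equation(eq)
                if rev != (rev_flag == "1"):
                    raise ValueError("reversible flag disagrees with arrow")
                reactions.append(Reaction(id=rid, stoichiometry=stoich,
                                          reversible=rev))
        except ValueError as exc:
            raise ValueError(f"{path.name}:{lineno}: {exc}") from None
    return MetabolicNetwork(metabolites=metabolites, reactions=reactions)


def save_network(network: MetabolicNetwork, path) -> None:
    lines = ["# shikflux network TSV"]
    for m in network.metabolites:
        lines.append(f"@metabolite\t{m.id}\t{m.name}\t{1 if m.external else 0}")
    for r in network.reactions:
        lines.append(f"{r.id}\t{1 if r.reversible else 0}\t{r.equation()}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_fixture_network() -> MetabolicNetwork:
    """Load the packaged synthetic 60/44/6 central-carbon network."""
    ref = resources.files("shikflux.data").joinpath(FIXTURE_NAME)
    with resources.as_file(ref) as p:
        return load_network(p)


def stoichiometric_matrix(network: MetabolicNetwork) -> np.ndarray:
    """Internal stoichiometric matrix: rows = internal metabolites in
    declaration order, columns = reactions in declaration order."""
    internal = [m.id for m in network.internal_metabolites]
    idx = {m: i for i, m in enumerate(internal)}
    s = np.zeros((len(internal), len(network.reactions)))
    for j, r in enumerate(network.reactions):
        for met, c in r.stoichiometry.items():
            if met in idx:
                s[idx[met], j] = c
    return s


#: Default yeast-extract decomposition coefficients (fixture constants):
#: fraction of YE mass going to the biomass-precursor pool, the lumped
#: aromatic amino acids, alanine and glutamate.
DEFAULT_YE_COEFFS = {"biomp": 0.6, "aaa": 0.4, "ala": 0.5, "glu": 0.5}


def ye_decomposition(coefficients: dict | None = None) -> list:
    """Yeast-extract uptake reactions yielding BIOMp, AAA, ALA and GLU.

    Two uptake reactions split YE into the protein-precursor pool (BIOMp +
    aromatic amino acids) and the free-amino-acid pool (ALA + GLU); exactly
    four product species overall.
    """
    c = dict(DEFAULT_YE_COEFFS)
    if coefficients:
        c.update(coefficients)
    for key in ("biomp", "aaa", "ala", "glu"):
        if c.get(key, 0) <= 0:
            raise ValueError(f"YE coefficient {key!r} must be positive")
    return [
        Reaction(id="YEup1", stoichiometry={"YE": -1.0, "BIOMp": c["biomp"],
                                            "AAA": c["aaa"]}),
        Reaction(id="YEup2", stoichiometry={"YE": -1.0, "ALA": c["ala"],
                                            "GLU": c["glu"]}),
    ]


def apply_ye_decomposition(network: MetabolicNetwork,
                           coefficients: dict | None = None) -> MetabolicNetwork:
    """Return a copy of the network with its YE uptake reactions replaced;
    metabolite and reaction counts are unchanged."""
    new_ye = {r.id: r for r in ye_decomposition(coefficients)}
    reactions = [new_ye.get(r.id, r) for r in network.reactions]
    return MetabolicNetwork(metabolites=list(network.metabolites),
                            reactions=reactions)


def validate(network: MetabolicNetwork) -> dict:
    """Structural report: orphan internal metabolites, disconnected reactions,
    duplicate stoichiometries.  Report-only, never raises."""
    report = {"orphan_metabolites": [], "disconnected_reactions": [],
              "duplicate_stoichiometries": [], "warnings": []}
    if not network.reactions:
        report["warnings"].append("empty network")
        return report
    produced, consumed = set(), set()
    for r in network.reactions:
        for met, c in r.stoichiometry.items():
            (produced if c > 0 else consumed).add(met)
        if r.reversible:
            for met in r.stoichiometry:
                produced.add(met)
                consumed.add(met)
    for m in network.internal_metabolites:
        if m.id not in produced or m.id not in consumed:
            report["orphan_metabolites"].append(m.id)
    seen: dict = {}
    for r in network.reactions:
        key = (r.reversible,
               tuple(sorted((k, round(v, 12)) for k, v in r.stoichiometry.items())))
        if key in seen:
            report["duplicate_stoichiometries"].append((seen[key], r.id))
        else:
            seen[key] = r.id
    # a reaction is disconnected when none of its metabolites occur elsewhere
    usage: dict = {}
    for r in network.reactions:
        for met in r.stoichiometry:
            usage.setdefault(met, set()).add(r.id)
    for r in network.reactions:
        if all(usage[met] == {r.id} for met in r.stoichiometry):
            report["disconnected_reactions"].append(r.id)
    return report
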