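"""Readers and writers for models, universal databases, annotations, media.

Model TSV dialect (one record per line, tab-separated, ``#`` comments):

    G   <genome_id>
    B   <biomass_reaction_id>
    M   <met_id>   <name>   <compartment>
    R   <rxn_id>   <stoich> <lb>  <ub>  <gpr>  <gapfilled>  <exchange>

``<stoich>`` is ``coef:met_id`` pairs joined by ``;`` with rational
coefficients (e.g. ``-1:A_c;1/2:B_c``).  ``<gpr>`` is a disjunction of
conjunctions, ``|``-joined terms of ``&``-joined gene ids, ``-`` if empty.
Writers emit records in canonical (lexicographic-by-id) order so that
write(read(f)) is byte-identical to the canonicalized file.
"""

from __future__ import annotations

import json
from fractions import Fraction
from pathlib import Path
from typing import Iterable

from .model import (
    GenomeAnnotation,
    Medium,
    Metabolite,
    ModelParseError,
    Reaction,
    StoichiometricModel,
    UniversalDatabase,
    require_valid,
)

# ---------------------------------------------------------------------------
# small field codecs


def format_stoichiometry(stoich: dict[str, Fraction]) -> str:
    return ";".join(f"{stoich[m]}:{m}" for m in sorted(stoich))


def parse_stoichiometry(text: str, where: str = "") -> dict[str, Fraction]:
    out: dict[str, Fraction] = {}
    for part in text.split(";"):
        part = part.strip()
        if not part:
            continue
        try:
            coef, met = part.split(":", 1)
            out[met.strip()] = Fraction(coef.strip())
        except (ValueError, ZeroDivisionError) as exc:
            raise ModelParseError(
                f"malformed stoichiometry term {part!r}{where}: {exc}"
            ) from None
    if not out:
        raise ModelParseError(f"empty stoichiometry{where}")
    return out


def format_gpr(gpr) -> str:
    if not gpr:
        return "-"
    return "|".join("&".join(conj) for conj in gpr)


def parse_gpr(text: str):
    text = text.strip()
    if text in ("", "-"):
        return ()
    return tuple(
        tuple(g.strip() for g in term.split("&")) for term in text.split("|")
    )


def _format_bound(x: float) -> str:
    return repr(float(x))


# ---------------------------------------------------------------------------
# model TSV / JSON


def model_to_tsv(model: StoichiometricModel) -> str:
    lines = ["# genomedecay model v1"]
    lines.append(f"G\t{model.genome_id}")
    lines.append(f"B\t{model.biomass_reaction_id}")
    for mid in model.metabolite_ids:
        met = model.metabolites[mid]
        lines.append(f"M\t{met.id}\t{met.name}\t{met.compartment}")
    for rid in model.reaction_ids:
        r = model.reactions[rid]
        lines.append(
            "R\t{id}\t{st}\t{lb}\t{ub}\t{gpr}\t{gf}\t{ex}".format(
                id=r.id,
                st=format_stoichiometry(r.stoichiometry),
                lb=_format_bound(r.lower_bound),
                ub=_format_bound(r.upper_bound),
                gpr=format_gpr(r.gene_association),
                gf=int(r.gapfilled),
                ex=int(r.is_exchange),
            )
        )
    return "\n".join(lines) + "\n"


def model_from_tsv(text: str) -> StoichiometricModel:
    genome_id = None
    biomass_id = None
    metabolites: list[Metabolite] = []
    reactions: list[Reaction] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        tag = fields[0]
        where = f" (line {lineno})"
        try:
            if tag == "G":
                genome_id = fields[1]
            elif tag == "B":
                biomass_id = fields[1]
            elif tag == "M":
                metabolites.append(
                    Metabolite(id=fields[1], name=fields[2],
                               compartment=fields[3]))
            elif tag == "R":
                reactions.append(Reaction(
                    id=fields[1],
                    stoichiometry=parse_stoichiometry(fields[2], where),
                    lower_bound=float(fields[3]),
                    upper_bound=float(fields[4]),
                    gene_association=parse_gpr(fields[5]),
                    gapfilled=bool(int(fields[6])),
                    is_exchange=bool(int(fields[7])),
                ))
            else:
                raise ModelParseError(f"unknown record tag {tag!r}{where}")
        except IndexError:
            raise ModelParseError(
                f"truncated {tag!r} record{where}") from None
    if genome_id is None:
        raise ModelParseError("missing G (genome id) record")
    if biomass_id is None:
        raise ModelParseError("missing B (biomass reaction) record")
    model = StoichiometricModel.from_components(
        genome_id, metabolites, reactions, biomass_id)
    require_valid(model)
    return model


def _reaction_to_dict(r: Reaction) -> dict:
    return {
        "id": r.id,
        "stoichiometry": {m: str(c) for m, c in sorted(r.stoichiometry.items())},
        "lower_bound": r.lower_bound,
        "upper_bound": r.upper_bound,
        "gene_association": [list(t) for t in r.gene_association],
        "gapfilled": r.gapfilled,
        "is_exchange": r.is_exchange,
    }


def _reaction_from_dict(d: dict) -> Reaction:
    return Reaction(
        id=d["id"],
        stoichiometry={m: Fraction(c) for m, c in d["stoichiometry"].items()},
        lower_bound=float(d["lower_bound"]),
        upper_bound=float(d["upper_bound"]),
        gene_association=tuple(tuple(t) for t in d.get("gene_association", [])),
        gapfilled=bool(d.get("gapfilled", False)),
        is_exchange=bool(d.get("is_exchange", False)),
    )


def model_to_json(model: StoichiometricModel) -> str:
    doc = {
        "genome_id": model.genome_id,
        "biomass_reaction_id": model.biomass_reaction_id,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in (model.metabolites[i] for i in model.metabolite_ids)
        ],
        "reactions": [
            _reaction_to_dict(model.reactions[i]) for i in model.reaction_ids
        ],
    }
    return json.dumps(doc, indent=1, sort_keys=True) + "\n"


def model_from_json(text: str) -> StoichiometricModel:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ModelParseError(f"invalid model JSON: {exc}") from None
    model = StoichiometricModel.from_components(
        doc["genome_id"],
        [Metabolite(**m) for m in doc["metabolites"]],
        [_reaction_from_dict(r) for r in doc["reactions"]],
        doc["biomass_reaction_id"],
    )
    require_valid(model)
    return model


def read_model(path, format: str | None = None) -> StoichiometricModel:
    path = Path(path)
    fmt = format or ("json" if path.suffix == ".json" else "tsv")
    text = path.read_text()
    if fmt == "json":
        return model_from_json(text)
    if fmt == "tsv":
        return model_from_tsv(text)
    raise ValueError(f"unknown model format {fmt!r}")


def write_model(model: StoichiometricModel, path, format: str | None = None
                ) -> None:
    require_valid(model)
    path = Path(path)
    fmt = format or ("json" if path.suffix == ".json" else "tsv")
    if fmt == "json":
        path.write_text(model_to_json(model))
    elif fmt == "tsv":
        path.write_text(model_to_tsv(model))
    else:
        raise ValueError(f"unknown model format {fmt!r}")


# ---------------------------------------------------------------------------
# universal database JSON


def database_to_json(db: UniversalDatabase) -> str:
    doc = {
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for _, m in sorted(db.metabolites.items())
        ],
        "reactions": [
            _reaction_to_dict(db.reactions[i]) for i in sorted(db.reactions)
        ],
        "role_map": {r: sorted(v) for r, v in sorted(db.role_map.items())},
        "transportable": sorted(db.transportable),
        "biomass_reaction_id": db.biomass_reaction_id,
    }
    return json.dumps(doc, indent=1, sort_keys=True) + "\n"


def database_from_json(text: str) -> UniversalDatabase:
    doc = json.loads(text)
    db = UniversalDatabase(
        metabolites={m["id"]: Metabolite(**m) for m in doc["metabolites"]},
        reactions={r["id"]: _reaction_from_dict(r) for r in doc["reactions"]},
        role_map={r: frozenset(v) for r, v in doc["role_map"].items()},
        transportable=frozenset(doc["transportable"]),
        biomass_reaction_id=doc["biomass_reaction_id"],
    )
    problems = db.validate()
    if problems:
        raise ModelParseError("invalid database: " + "; ".join(problems))
    return db


def read_database(path) -> UniversalDatabase:
    return database_from_json(Path(path).read_text())


def write_database(db: UniversalDatabase, path) -> None:
    Path(path).write_text(database_to_json(db))


# ---------------------------------------------------------------------------
# annotations, media


def annotations_to_tsv(annotations: Iterable[GenomeAnnotation]) -> str:
    lines = ["genome_id\tgene_id\trole"]
    for ann in annotations:
        for gene, role in ann.genes:
            lines.append(f"{ann.genome_id}\t{gene}\t{role}")
    return "\n".join(lines) + "\n"


def annotations_from_tsv(text: str) -> dict[str, GenomeAnnotation]:
    rows: dict[str, list[tuple[str, str]]] = {}
    lines = text.splitlines()
    if not lines or lines[0].split("\t")[:3] != ["genome_id", "gene_id", "role"]:
        raise ModelParseError(
            "annotation TSV must start with header genome_id<TAB>gene_id<TAB>role")
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ModelParseError(f"annotation line {lineno}: expected 3 columns")
        rows.setdefault(fields[0], []).append((fields[1], fields[2]))
    return {
        g: GenomeAnnotation(genome_id=g, genes=tuple(pairs))
        for g, pairs in rows.items()
    }


def read_annotations(path) -> dict[str, GenomeAnnotation]:
    return annotations_from_tsv(Path(path).read_text())


def write_annotations(annotations: Iterable[GenomeAnnotation], path) -> None:
    Path(path).write_text(annotations_to_tsv(annotations))


def medium_to_tsv(medium: Medium) -> str:
    lines = [f"# uptake_limit\t{medium.uptake_limit!r}", "nutrient"]
    lines.extend(sorted(medium.nutrients))
    return "\n".join(lines) + "\n"


def medium_from_tsv(text: str) -> Medium:
    uptake = 10.0
    nutrients = []
    for line in text.splitlines():
        if line.startswith("# uptake_limit"):
            uptake = float(line.split("\t")[1])
        elif line.strip() and not line.startswith("#") and line != "nutrient":
            nutrients.append(line.strip())
    return Medium(nutrients=frozenset(nutrients), uptake_limit=uptake)


def read_medium(path) -> Medium:
    return medium_from_tsv(Path(path).read_text())


def write_medium(medium: Medium, path) -> None:
    Path(path).write_text(medium_to_tsv(medium))
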