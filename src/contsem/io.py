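"""Document readers and writers.

One self-describing JSON format holds an instance document (continuants,
states, events, continuations in a single file, so that boundary
coincidences are locally checkable); signatures travel in a separate,
equally self-contained file.  Instants are serialized as strings of
integers or fractions ("3", "7/2"); parsing preserves exactness, and bare
float literals are rejected unless decimal conversion is explicitly
allowed (in which case "0.1" becomes exactly 1/10).

Serialization is canonical — fixed key order, registries sorted by id,
atom sets sorted — so ``dumps(loads(text)) == text`` for canonical-form
documents.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Any, Optional, Sequence, Union

import yaml

from .errors import ExactnessError, SchemaError
from .model import (
    AnomalyFinding,
    Continuant,
    ContinuantType,
    Continuation,
    ContinuationSignature,
    ContinuationType,
    Dependency,
    Document,
    EventInstance,
    Participation,
    StateAtom,
    StateOfAffairs,
    StateType,
)
from .temporal import (
    Interval,
    TemporalExtent,
    as_instant,
    format_instant,
)

DOCUMENT_FORMAT = "contsem-document/1"
SIGNATURE_FORMAT = "contsem-signature/1"


@dataclass
class Config:
    """Run-time configuration, loadable from YAML.

    ``transitive_subevents`` selects the mereological reading of the
    subevent relation; ``rest_grid`` expands rest continuations into a
    δ-grid when generating contraction fixtures; ``allow_decimal`` permits
    decimal literals in documents (converted exactly).
    """

    transitive_subevents: bool = True
    rest_grid: Optional[Fraction] = None
    allow_decimal: bool = False


def load_config(path: Union[str, Path]) -> Config:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise SchemaError("$", "config must be a mapping")
    cfg = Config()
    if "transitive_subevents" in raw:
        cfg.transitive_subevents = bool(raw["transitive_subevents"])
    if "rest_grid" in raw and raw["rest_grid"] is not None:
        cfg.rest_grid = as_instant(str(raw["rest_grid"]))
    if "allow_decimal" in raw:
        cfg.allow_decimal = bool(raw["allow_decimal"])
    return cfg


# ---------------------------------------------------------------------------
# parsing helpers
# ---------------------------------------------------------------------------

def _parse_json(text: str, allow_decimal: bool) -> Any:
    def reject(tok: str) -> Fraction:
        raise ExactnessError(
            "$", f"decimal literal {tok} would be read as a binary float; "
                 f"quote it as a string or enable allow_decimal for exact "
                 f"decimal conversion")

    parse_float = Fraction if allow_decimal else reject
    try:
        return json.loads(text, parse_float=parse_float)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"$ (line {exc.lineno})", f"invalid JSON: {exc.msg}") from exc


def _req(obj: dict, key: str, path: str) -> Any:
    if not isinstance(obj, dict):
        raise SchemaError(path, f"expected an object, got {type(obj).__name__}")
    if key not in obj:
        raise SchemaError(f"{path}/{key}", "required key missing")
    return obj[key]


def _instant(value: Any, path: str) -> Fraction:
    if isinstance(value, bool) or not isinstance(value, (str, int, Fraction)):
        raise SchemaError(path, f"not an exact instant: {value!r}")
    try:
        return as_instant(value)
    except ExactnessError as exc:
        raise SchemaError(path, str(exc)) from exc


def _interval(value: Any, path: str) -> Interval:
    if not isinstance(value, (list, tuple)) or len(value) != 2:
        raise SchemaError(path, "an interval is a two-element array")
    return Interval(_instant(value[0], f"{path}/0"),
                    _instant(value[1], f"{path}/1"))


def _extent(value: Any, path: str) -> TemporalExtent:
    if not isinstance(value, (list, tuple)):
        raise SchemaError(path, "an extent is an array of intervals")
    return TemporalExtent(tuple(_interval(iv, f"{path}/{i}")
                                for i, iv in enumerate(value)))


def _atom(value: Any, path: str) -> StateAtom:
    bearer = _req(value, "bearer", path)
    quality = _req(value, "quality", path)
    val = _req(value, "value", path)
    if isinstance(val, bool) or not isinstance(val, (str, int)):
        raise SchemaError(f"{path}/value", "atom value must be a label or integer")
    return StateAtom(str(bearer), str(quality), val)


def _records(raw: dict, key: str) -> list[tuple[dict, str]]:
    items = raw.get(key, [])
    if not isinstance(items, list):
        raise SchemaError(f"/{key}", "expected an array")
    return [(item, f"/{key}/{i}") for i, item in enumerate(items)]


# ---------------------------------------------------------------------------
# document I/O
# ---------------------------------------------------------------------------

def loads_document(text: str, allow_decimal: bool = False) -> Document:
    """Parse, schema-check and referentially validate a document."""
    raw = _parse_json(text, allow_decimal)
    if not isinstance(raw, dict):
        raise SchemaError("$", "document root must be an object")
    fmt = raw.get("format")
    if fmt != DOCUMENT_FORMAT:
        raise SchemaError("/format", f"expected {DOCUMENT_FORMAT!r}, got {fmt!r}")
    doc = Document(unit=raw.get("unit"))

    for item, path in _records(raw, "continuant_types"):
        doc.add(ContinuantType(id=str(_req(item, "id", path)),
                               label=str(item.get("label", ""))))
    for item, path in _records(raw, "continuants"):
        doc.add(Continuant(
            id=str(_req(item, "id", path)), label=str(item.get("label", "")),
            kind=str(item.get("kind", "independent")),
            types=tuple(item.get("types", []))))
    for item, path in _records(raw, "states"):
        atoms = _req(item, "atoms", path)
        doc.add(StateOfAffairs(
            id=str(_req(item, "id", path)),
            atoms=frozenset(_atom(a, f"{path}/atoms/{i}")
                            for i, a in enumerate(atoms))))
    for item, path in _records(raw, "state_types"):
        templates = _req(item, "templates", path)
        doc.add(StateType(
            id=str(_req(item, "id", path)),
            templates=frozenset(_atom(a, f"{path}/templates/{i}")
                                for i, a in enumerate(templates))))
    for item, path in _records(raw, "continuation_types"):
        doc.add(ContinuationType(
            id=str(_req(item, "id", path)), label=str(item.get("label", "")),
            context_state_type=item.get("context_state_type")))
    for item, path in _records(raw, "events"):
        participants = []
        for i, p in enumerate(item.get("participants", [])):
            ppath = f"{path}/participants/{i}"
            participants.append(Participation(
                participant=str(_req(p, "participant", ppath)),
                interval=_interval(_req(p, "interval", ppath),
                                   f"{ppath}/interval"),
                generic=bool(p.get("generic", False))))
        doc.add(EventInstance(
            id=str(_req(item, "id", path)),
            extent=_extent(_req(item, "extent", path), f"{path}/extent"),
            parent=item.get("parent"),
            participants=tuple(participants),
            initial_state=item.get("initial_state"),
            final_state=item.get("final_state"),
            made_of_process=item.get("made_of_process")))
    for item, path in _records(raw, "continuations"):
        deps = frozenset(
            Dependency(target=str(_req(d, "target", f"{path}/dependencies/{i}")),
                       generic=bool(d.get("generic", False)))
            for i, d in enumerate(item.get("dependencies", [])))
        doc.add(Continuation(
            id=str(_req(item, "id", path)),
            life_time=_extent(_req(item, "life_time", path),
                              f"{path}/life_time"),
            context_state=str(_req(item, "context_state", path)),
            completed_subevent=str(_req(item, "completed_subevent", path)),
            succeeding_subevent=str(_req(item, "succeeding_subevent", path)),
            ctype=str(_req(item, "ctype", path)),
            dependencies=deps,
            canonical_duration=_instant(item.get("canonical_duration", 0),
                                        f"{path}/canonical_duration")))
    doc.validate_or_raise()
    return doc


def load_document(path: Union[str, Path], allow_decimal: bool = False) -> Document:
    return loads_document(Path(path).read_text(), allow_decimal=allow_decimal)


def _dump_interval(iv: Interval) -> list[str]:
    return [format_instant(iv.start), format_instant(iv.end)]


def _dump_extent(x: TemporalExtent) -> list[list[str]]:
    return [_dump_interval(ep) for ep in x.episodes]


def _dump_atom(a: StateAtom) -> dict:
    return {"bearer": a.bearer, "quality": a.quality, "value": a.value}


def _sorted_atoms(atoms: frozenset[StateAtom]) -> list[dict]:
    return [_dump_atom(a) for a in
            sorted(atoms, key=lambda a: (a.bearer, a.quality, str(a.value)))]


def dumps_document(doc: Document) -> str:
    """Canonical serialization (sorted registries, fixed key order)."""
    out: dict[str, Any] = {"format": DOCUMENT_FORMAT, "unit": doc.unit}
    out["continuant_types"] = [
        {"id": t.id, "label": t.label}
        for t in sorted(doc.continuant_types.values(), key=lambda t: t.id)]
    out["continuants"] = [
        {"id": c.id, "label": c.label, "kind": c.kind, "types": sorted(c.types)}
        for c in sorted(doc.continuants.values(), key=lambda c: c.id)]
    out["states"] = [
        {"id": s.id, "atoms": _sorted_atoms(s.atoms)}
        for s in sorted(doc.states.values(), key=lambda s: s.id)]
    out["state_types"] = [
        {"id": s.id, "templates": _sorted_atoms(s.templates)}
        for s in sorted(doc.state_types.values(), key=lambda s: s.id)]
    out["continuation_types"] = [
        {"id": t.id, "label": t.label, "context_state_type": t.context_state_type}
        for t in sorted(doc.continuation_types.values(), key=lambda t: t.id)]
    out["events"] = [
        {"id": e.id, "extent": _dump_extent(e.extent), "parent": e.parent,
         "participants": [
             {"participant": p.participant,
              "interval": _dump_interval(p.interval), "generic": p.generic}
             for p in e.participants],
         "initial_state": e.initial_state, "final_state": e.final_state,
         "made_of_process": e.made_of_process}
        for e in sorted(doc.events.values(), key=lambda e: e.id)]
    out["continuations"] = [
        {"id": k.id, "life_time": _dump_extent(k.life_time),
         "context_state": k.context_state,
         "completed_subevent": k.completed_subevent,
         "succeeding_subevent": k.succeeding_subevent,
         "ctype": k.ctype,
         "dependencies": [
             {"target": d.target, "generic": d.generic}
             for d in sorted(k.dependencies, key=lambda d: (d.target, d.generic))],
         "canonical_duration": format_instant(k.canonical_duration)}
        for k in sorted(doc.continuations.values(), key=lambda k: k.id)]
    return json.dumps(out, indent=2) + "\n"


def dump_document(doc: Document, path: Union[str, Path]) -> None:
    Path(path).write_text(dumps_document(doc))


# ---------------------------------------------------------------------------
# signature I/O
# ---------------------------------------------------------------------------

def loads_signature(text: str) -> ContinuationSignature:
    raw = _parse_json(text, allow_decimal=False)
    if not isinstance(raw, dict):
        raise SchemaError("$", "signature root must be an object")
    if raw.get("format") != SIGNATURE_FORMAT:
        raise SchemaError("/format",
                          f"expected {SIGNATURE_FORMAT!r}, got {raw.get('format')!r}")
    fst = _req(raw, "final_state_type", "$")
    final_type = StateType(
        id=str(_req(fst, "id", "/final_state_type")),
        templates=frozenset(
            _atom(a, f"/final_state_type/templates/{i}")
            for i, a in enumerate(_req(fst, "templates", "/final_state_type"))))
    registry = {}
    for item, path in _records(raw, "continuation_types"):
        t = ContinuationType(
            id=str(_req(item, "id", path)), label=str(item.get("label", "")),
            context_state_type=item.get("context_state_type"))
        registry[t.id] = t
    ordered = _req(raw, "ordered_types", "$")
    if not isinstance(ordered, list):
        raise SchemaError("/ordered_types", "expected an array of type ids")
    return ContinuationSignature(
        id=str(_req(raw, "id", "$")), ordered_types=tuple(map(str, ordered)),
        final_state_type=final_type, type_registry=registry)


def load_signature(path: Union[str, Path]) -> ContinuationSignature:
    return loads_signature(Path(path).read_text())


def dumps_signature(sig: ContinuationSignature) -> str:
    out = {
        "format": SIGNATURE_FORMAT,
        "id": sig.id,
        "ordered_types": list(sig.ordered_types),
        "continuation_types": [
            {"id": t.id, "label": t.label,
             "context_state_type": t.context_state_type}
            for t in sorted(sig.type_registry.values(), key=lambda t: t.id)],
        "final_state_type": {
            "id": sig.final_state_type.id,
            "templates": _sorted_atoms(sig.final_state_type.templates)},
    }
    return json.dumps(out, indent=2) + "\n"


def dump_signature(sig: ContinuationSignature, path: Union[str, Path]) -> None:
    Path(path).write_text(dumps_signature(sig))


# ---------------------------------------------------------------------------
# anomaly reports
# ---------------------------------------------------------------------------

REPORT_COLUMNS = ("event_id", "kind", "start", "end", "duration",
                  "evidencing_continuation", "term", "clauses_satisfied")


def _finding_row(f: AnomalyFinding) -> dict:
    return {
        "event_id": f.affected_event,
        "kind": f.kind,
        "start": format_instant(f.episode.start),
        "end": format_instant(f.episode.end),
        "duration": format_instant(f.episode.length),
        "evidencing_continuation": f.evidencing_continuation or "",
        "term": f.term or "",
        "clauses_satisfied": ",".join(f.justification),
    }


def write_report(findings: Sequence[AnomalyFinding], format: str = "json") -> str:
    """Render findings as a stable-field-order JSON array or a TSV table."""
    if format == "tsv":
        lines = ["\t".join(REPORT_COLUMNS)]
        for f in findings:
            row = _finding_row(f)
            lines.append("\t".join(str(row[c]) for c in REPORT_COLUMNS))
        return "\n".join(lines) + "\n"
    if format == "json":
        payload = []
        for f in findings:
            row = _finding_row(f)
            row["annotation_target"] = f.annotation_target
            row["unconfirmed"] = f.unconfirmed
            payload.append(row)
        return json.dumps(payload, indent=2) + "\n"
    raise ValueError(f"unknown report format {format!r}")


def findings_from_json(text: str) -> list[AnomalyFinding]:
    """Inverse of the JSON report: reconstruct findings from a report."""
    raw = _parse_json(text, allow_decimal=False)
    out = []
    for i, row in enumerate(raw):
        path = f"/{i}"
        out.append(AnomalyFinding(
            kind=str(_req(row, "kind", path)),
            episode=Interval(_instant(_req(row, "start", path), path),
                             _instant(_req(row, "end", path), path)),
            evidencing_continuation=row.get("evidencing_continuation") or None,
            affected_event=str(_req(row, "event_id", path)),
            justification=tuple(x for x in
                                str(row.get("clauses_satisfied", "")).split(",") if x),
            term=row.get("term") or None,
            annotation_target=row.get("annotation_target"),
            unconfirmed=bool(row.get("unconfirmed", False))))
    return out
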