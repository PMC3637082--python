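"""Declarative guideline knowledge: rules, vocabulary, translations, documents.

Clinical content is data, not code.  Thresholds (elevated blood pressure,
anaemia cut-offs, fetal-heart-rate bands, ...) live in a versioned YAML
rule file together with the controlled observation vocabulary, so the
knowledge can be audited and replaced without touching engine logic.
Each rule cites its source document and section; sources resolve against
a document registry whose training entries are open-access (no password).

A rule's condition is a finite tree of predicates (code, comparator,
threshold) combined with ``all`` / ``any`` / ``not`` blocks.  Two severity
tiers exist: ``instant_watchdog`` rules fire the moment a triggering value
is entered, ``end_of_visit`` rules integrate the whole record at visit
finalization.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

from .errors import RuleSetError, UnknownKeyError, ValidationError

COMPARATORS = ("eq", "ne", "lt", "le", "gt", "ge", "present", "absent")
NUMERIC_COMPARATORS = ("lt", "le", "gt", "ge")
SEVERITIES = ("instant_watchdog", "end_of_visit")
ACTION_KINDS = ("exam", "treatment", "referral", "counselling", "preventive")


@dataclass(frozen=True)
class Predicate:
    code: str
    op: str
    value: Union[int, float, bool, str, None] = None


@dataclass(frozen=True)
class Combinator:
    op: str  # all | any | not
    children: tuple


ConditionNode = Union[Predicate, Combinator]


@dataclass(frozen=True)
class ActionProposal:
    kind: str
    description_key: str


@dataclass(frozen=True)
class SourceRef:
    document_id: str
    section_label: str


@dataclass(frozen=True)
class Rule:
    rule_id: str
    severity: str
    condition: ConditionNode
    message_key: str
    actions: tuple  # of ActionProposal
    source: SourceRef


@dataclass(frozen=True)
class VocabEntry:
    code: str
    kind: str  # numeric | boolean | category
    unit: str = ""
    label: str = ""


def condition_codes(node: ConditionNode) -> set:
    """All observation codes referenced anywhere in a condition tree."""
    if isinstance(node, Predicate):
        return {node.code}
    out: set = set()
    for child in node.children:
        out |= condition_codes(child)
    return out


def condition_predicates(node: ConditionNode) -> list:
    if isinstance(node, Predicate):
        return [node]
    preds: list = []
    for child in node.children:
        preds.extend(condition_predicates(child))
    return preds


@dataclass
class RuleSet:
    version: str
    guideline: str
    vocabulary: dict  # code -> VocabEntry
    rules: tuple  # of Rule, already in firing-priority order

    def rule(self, rule_id: str) -> Rule:
        for r in self.rules:
            if r.rule_id == rule_id:
                return r
        raise KeyError(rule_id)

    def watchdogs(self) -> tuple:
        return tuple(r for r in self.rules if r.severity == "instant_watchdog")

    def end_of_visit_rules(self) -> tuple:
        return tuple(r for r in self.rules if r.severity == "end_of_visit")


def _parse_condition(raw, vocabulary: dict, rule_id: str) -> ConditionNode:
    if not isinstance(raw, dict):
        raise RuleSetError(f"rule {rule_id!r}: condition node must be a mapping")
    combos = [k for k in ("all", "any", "not") if k in raw]
    if combos:
        op = combos[0]
        children = raw[op]
        if op == "not":
            children = [children] if isinstance(children, dict) else children
            if len(children) != 1:
                raise RuleSetError(
                    f"rule {rule_id!r}: 'not' takes exactly one child")
        if not isinstance(children, list) or not children:
            raise RuleSetError(
                f"rule {rule_id!r}: {op!r} needs a non-empty list of children")
        return Combinator(op, tuple(
            _parse_condition(c, vocabulary, rule_id) for c in children))
    code = raw.get("code")
    op = raw.get("op")
    if code not in vocabulary:
        raise RuleSetError(
            f"rule {rule_id!r} references unknown observation code {code!r}")
    if op not in COMPARATORS:
        raise RuleSetError(f"rule {rule_id!r}: unknown comparator {op!r}")
    entry = vocabulary[code]
    if op in NUMERIC_COMPARATORS and entry.kind != "numeric":
        raise RuleSetError(
            f"rule {rule_id!r}: comparator {op!r} requires numeric code, "
            f"{code!r} is {entry.kind}")
    value = raw.get("value")
    if op in NUMERIC_COMPARATORS + ("eq", "ne") and value is None:
        raise RuleSetError(
            f"rule {rule_id!r}: comparator {op!r} needs a threshold value")
    return Predicate(code, op, value)


def _rule_sort_key(rule: Rule):
    # watchdogs first, then lexicographic id: the stable firing order
    return (SEVERITIES.index(rule.severity), rule.rule_id)


def parse_ruleset(data: dict, *, origin: str = "<memory>") -> RuleSet:
    if not isinstance(data, dict):
        raise RuleSetError(f"{origin}: rule file must be a mapping")
    meta = data.get("meta") or {}
    vocab_raw = data.get("vocabulary") or {}
    vocabulary = {}
    for code, spec in vocab_raw.items():
        spec = spec or {}
        kind = spec.get("kind", "numeric")
        if kind not in ("numeric", "boolean", "category"):
            raise RuleSetError(f"vocabulary {code!r}: unknown kind {kind!r}")
        vocabulary[code] = VocabEntry(code=code, kind=kind,
                                      unit=spec.get("unit", ""),
                                      label=spec.get("label", ""))
    rules = []
    seen = set()
    for raw in data.get("rules") or []:
        rid = raw.get("id")
        if not rid:
            raise RuleSetError(f"{origin}: rule without an id")
        if rid in seen:
            raise RuleSetError(f"{origin}: duplicate rule id {rid!r}")
        seen.add(rid)
        severity = raw.get("severity")
        if severity not in SEVERITIES:
            raise RuleSetError(f"rule {rid!r}: unknown severity {severity!r}")
        condition = _parse_condition(raw.get("condition"), vocabulary, rid)
        actions = []
        for a in raw.get("actions") or []:
            kind = a.get("kind")
            if kind not in ACTION_KINDS:
                raise RuleSetError(f"rule {rid!r}: unknown action kind {kind!r}")
            actions.append(ActionProposal(kind, a.get("description_key", "")))
        src = raw.get("source") or {}
        if not src.get("document_id"):
            raise RuleSetError(f"rule {rid!r}: missing source document_id")
        rules.append(Rule(
            rule_id=rid, severity=severity, condition=condition,
            message_key=raw.get("message_key", f"rule.{rid}"),
            actions=tuple(actions),
            source=SourceRef(src["document_id"], src.get("section", ""))))
    rules.sort(key=_rule_sort_key)
    return RuleSet(version=str(meta.get("ruleset_version", "")),
                   guideline=str(meta.get("guideline", "")),
                   vocabulary=vocabulary, rules=tuple(rules))


def load_ruleset(path) -> RuleSet:
    """Load a rule file atomically: any defect rejects the whole set."""
    try:
        text = Path(path).read_text(encoding="utf-8")
    except OSError as exc:
        raise RuleSetError(f"cannot read rule file {path}: {exc}") from exc
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise RuleSetError(f"rule file {path} is not valid YAML: {exc}") from exc
    return parse_ruleset(data or {}, origin=str(path))


# --------------------------------------------------------- rule-set checking

def _candidate_states(rule: Rule, vocabulary: dict) -> list:
    """Small per-code value lattices covering every branch of the condition.

    For numeric codes the candidates are each mentioned threshold, one step
    below and above it, and 'missing'; booleans get {True, False, missing};
    categories get every mentioned literal plus an unmentioned one.
    """
    per_code: dict = {}
    for pred in condition_predicates(rule.condition):
        cands = per_code.setdefault(pred.code, {None})
        kind = vocabulary[pred.code].kind
        if kind == "numeric" and pred.value is not None:
            v = float(pred.value)
            cands.update({v - 1, v, v + 1})
        elif kind == "boolean":
            cands.update({True, False})
        else:
            if pred.value is not None:
                cands.add(pred.value)
            cands.add("__other__")
        if pred.op in ("present", "absent") and kind == "numeric":
            cands.add(1.0)
    codes = sorted(per_code)
    states = [{}]
    for code in codes:
        states = [dict(s, **({code: v} if v is not None else {}))
                  for s in states
                  for v in sorted(per_code[code], key=repr)]
    return states


def validate_ruleset(ruleset: RuleSet, *, catalog=None, registry=None) -> list:
    """Structural report: unreachable rules, unresolvable keys and sources.

    Reachability is decided by brute force over a small value lattice per
    referenced code (thresholds +/- one step, missing, boolean poles), which
    covers every comparison branch of the condition tree.
    """
    from .oracles import condition_oracle  # independent evaluator

    issues: list = []
    for rule in ruleset.rules:
        states = _candidate_states(rule, ruleset.vocabulary)
        if not any(condition_oracle(s, rule.condition) for s in states):
            issues.append(f"rule {rule.rule_id!r}: condition is unsatisfiable "
                          "over its predicate value lattice (unreachable)")
        if catalog is not None:
            for key in [rule.message_key] + [a.description_key
                                             for a in rule.actions]:
                try:
                    catalog.translate(key, catalog.default_language)
                except UnknownKeyError:
                    issues.append(
                        f"rule {rule.rule_id!r}: message key {key!r} not in "
                        "catalog")
        if registry is not None:
            try:
                registry.get(rule.source.document_id)
            except KeyError:
                issues.append(
                    f"rule {rule.rule_id!r}: source document "
                    f"{rule.source.document_id!r} not registered")
    return issues


# ------------------------------------------------------------- translations

class TranslationCatalog:
    """key -> language -> string, with fallback to the default language.

    The default language must cover every key; other languages may be
    partial.  ``translate`` never fails for a known key.
    """

    def __init__(self, table: dict, default_language: str = "en"):
        self.table = table
        self.default_language = default_language
        for key, langs in table.items():
            if default_language not in langs:
                raise ValidationError(
                    f"catalog key {key!r} lacks the default language "
                    f"{default_language!r}")

    @classmethod
    def load(cls, path) -> "TranslationCatalog":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls(data.get("messages", {}),
                   data.get("default_language", "en"))

    def languages(self) -> list:
        langs = {self.default_language}
        for entry in self.table.values():
            langs.update(entry)
        return sorted(langs)

    def translate(self, key: str, language: Optional[str] = None) -> str:
        entry = self.table.get(key)
        if entry is None:
            raise UnknownKeyError(
                key, difflib.get_close_matches(key, self.table, n=3))
        language = language or self.default_language
        return entry.get(language, entry[self.default_language])


# --------------------------------------------------------- document registry

@dataclass
class DocumentEntry:
    document_id: str
    title: str
    location: str  # file path or URL; references only, no document text
    access_level: str = "open"  # open | authenticated
    category: str = "guideline"  # guideline | training | local


class DocumentRegistry:
    """Registry of guideline and training documents.

    Training documents are open-access by definition — they can be listed
    and opened without any user context, so all site personnel can use them
    for self-study.
    """

    def __init__(self, entries=()):
        self._entries: dict = {}
        for e in entries:
            self.register(e)

    @classmethod
    def load(cls, path) -> "DocumentRegistry":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        reg = cls()
        for raw in data.get("documents", []):
            reg.register(DocumentEntry(
                document_id=raw["id"], title=raw.get("title", ""),
                location=raw.get("location", ""),
                access_level=raw.get("access_level", "open"),
                category=raw.get("category", "guideline")))
        return reg

    def register(self, entry: DocumentEntry) -> None:
        if entry.category == "training" and entry.access_level != "open":
            raise ValidationError(
                f"training document {entry.document_id!r} must be open-access")
        self._entries[entry.document_id] = entry

    def get(self, document_id: str) -> DocumentEntry:
        return self._entries[document_id]

    def list_documents(self, *, authenticated: bool = False) -> list:
        out = [e for e in self._entries.values()
               if authenticated or e.access_level == "open"]
        return sorted(out, key=lambda e: e.document_id)


def resolve_source(rule: Rule, registry: DocumentRegistry):
    """Follow a rule's citation to its registered document."""
    try:
        entry = registry.get(rule.source.document_id)
    except KeyError:
        raise ValidationError(
            f"rule {rule.rule_id!r} cites unregistered document "
            f"{rule.source.document_id!r}") from None
    return entry, rule.source.section_label
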