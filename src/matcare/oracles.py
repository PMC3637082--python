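"""Independent brute-force evaluators used as test oracles.

These deliberately share no code with the production paths they check:
:func:`condition_oracle` is a plain recursive interpreter of the condition
tree (the engine compiles conditions to closures), and
:func:`zone_oracle` re-derives the partograph zone from the raw line
formulas.  Keep them boring and obviously correct.
"""

from __future__ import annotations

import operator

_NUMERIC_OPS = {"lt": operator.lt, "le": operator.le,
                "gt": operator.gt, "ge": operator.ge}


def condition_oracle(state: dict, node) -> bool:
    """Recursive truth evaluation of a condition tree over a value map.

    ``state`` maps observation code -> latest value; a missing code makes
    any predicate on it false, except ``absent`` which is then true.
    """
    from .knowledge import Combinator, Predicate

    if isinstance(node, Combinator):
        results = [condition_oracle(state, c) for c in node.children]
        if node.op == "all":
            return all(results)
        if node.op == "any":
            return any(results)
        return not results[0]  # not
    assert isinstance(node, Predicate)
    value = state.get(node.code)
    if node.op == "present":
        return value is not None and value is not False
    if node.op == "absent":
        return value is None or value is False
    if value is None:
        return False
    if node.op in _NUMERIC_OPS:
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            return False
        return _NUMERIC_OPS[node.op](value, node.value)
    if node.op == "eq":
        return value == node.value
    if node.op == "ne":
        return value != node.value
    raise ValueError(f"unknown comparator {node.op!r}")


def zone_oracle(config, t: float, d: float) -> str:
    """Partograph zone straight from the line formulas.

    alert(t)  = min(D0 + s*t, full)
    action(t) = min(D0 + s*(t - delta), full), defined only for t >= delta.
    On the alert line is normal (crossing is strict); on the action line
    counts as crossed.
    """
    alert = min(config.onset_dilatation + config.line_slope * t,
                config.full_dilatation)
    if t >= config.action_offset:
        action = min(config.onset_dilatation
                     + config.line_slope * (t - config.action_offset),
                     config.full_dilatation)
        if d <= action:
            return "action"
    if d < alert:
        return "alert"
    return "normal"
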