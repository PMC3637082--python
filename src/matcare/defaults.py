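"""Access to the packaged reference configuration files.

Everything here is deployment-replaceable data: the rule set, the message
catalog, the document registry, the ANC checklist template and the visit
schedule.  Loaders cache per-process; the objects are treated as read-only.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources


def data_path(name: str):
    """Filesystem path of a packaged data file."""
    return resources.files("matcare.data") / name


@lru_cache(maxsize=None)
def default_ruleset():
    from .knowledge import load_ruleset
    return load_ruleset(data_path("ruleset.yaml"))


@lru_cache(maxsize=None)
def default_catalog():
    from .knowledge import TranslationCatalog
    return TranslationCatalog.load(data_path("translations.yaml"))


@lru_cache(maxsize=None)
def default_registry():
    from .knowledge import DocumentRegistry
    return DocumentRegistry.load(data_path("documents.yaml"))


@lru_cache(maxsize=None)
def default_template():
    from .anc import load_template
    return load_template(data_path("checklist.yaml"))


@lru_cache(maxsize=None)
def default_schedule():
    from .anc import load_schedule
    return load_schedule(data_path("schedule.yaml"))
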