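"""Packaged reference fixtures.

``preclinical_registry()`` — the 40 unique preclinical candidates for
pre-eclampsia prevention (16 rows) and treatment (29 rows), five of them
under investigation for both indications (Lovastatin, AP39, Trehalose,
Quercetin and Ad-VEGF), each with medicine subclass and archetype as
printed. Note: summing the archetype column gives 21 unique repurposed
candidates, one more than the summary figure of 20 (50%) reported
alongside the tables; the fixture carries the per-candidate table values
verbatim (see :data:`PRECLINICAL_ARCHETYPE_NOTE`). Per-candidate product
type and activity year are not part of the printed tables: product types
here are synthetic annotations assigned by an obvious drug-class
heuristic, and activity years are left absent.

``clinical_registry()`` — the 32 unique candidates in clinical development
that survived eligibility screening: for prevention, ten in phase III,
five in phase II and two in phase I; for treatment, four in phase III,
nine in phase II and six in phase I; esomeprazole, pravastatin, ozagrel
and metformin appear on both lists. Archetype and product-type columns
are plausible synthetic annotations (the source lists print names and
phases only); all screening flags are false by construction, since these
candidates already passed screening.
"""

from __future__ import annotations

from importlib import resources

from ..registry import Indication, Phase, Registry, load_registry

__all__ = [
    "PRECLINICAL_ARCHETYPE_NOTE",
    "clinical_phase_lists",
    "clinical_registry",
    "default_scheme_path",
    "preclinical_registry",
]

PRECLINICAL_ARCHETYPE_NOTE = (
    "Archetype column sums to 21 unique repurposed preclinical candidates; "
    "the printed summary reports 20 (50%). The fixture carries the "
    "per-candidate values verbatim and does not resolve the discrepancy."
)


def _fixture_path(name: str):
    return resources.files(__package__) / name


def preclinical_registry() -> Registry:
    """The transcribed preclinical candidate tables (40 unique rows)."""
    with resources.as_file(_fixture_path("preclinical_registry.csv")) as p:
        return load_registry(p)


def clinical_registry() -> Registry:
    """The 32 post-screening clinical candidates (one row per candidate)."""
    with resources.as_file(_fixture_path("clinical_registry.csv")) as p:
        return load_registry(p)


def clinical_phase_lists() -> dict[tuple[str, str], list[str]]:
    """The six per-indication, per-phase candidate name lists.

    Keys are ``(indication, phase)`` value pairs; dual-indication
    candidates appear in the list for each of their indications.
    """
    lists: dict[tuple[str, str], list[str]] = {
        (ind.value, ph.value): []
        for ind in Indication
        for ph in (Phase.III, Phase.II, Phase.I)
    }
    for cand in clinical_registry():
        for ind in sorted(cand.indications, key=lambda i: i.value):
            lists[(ind.value, cand.phase.value)].append(cand.name)
    return lists


def default_scheme_path():
    """Filesystem path of the packaged default scoring-scheme YAML."""
    return _fixture_path("default_scheme.yaml")
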