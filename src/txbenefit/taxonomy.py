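"""Hierarchical taxonomy of questionnaire dimensions and question grouping.

Questionnaire items from different instruments are tagged onto a custom
category tree (roots such as quality of life or symptom dimensions, with
branches and leaves beneath them).  Items judged to query the same
dimension are grouped into a single feature at the deepest category that
covers all of them; a declarative overrides file stands in for the
rater-consensus step, so the grouping is deterministic given its inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import yaml

__all__ = [
    "TaxonomyTree",
    "StandardQuestion",
    "FeatureGroup",
    "build_taxonomy",
    "tag_question",
    "resolve_group_category",
    "group_by_category",
    "default_taxonomy_spec",
]


class TaxonomyError(ValueError):
    pass


@dataclass(frozen=True)
class StandardQuestion:
    """A canonical question with scale, category tags and flags."""

    question_id: str
    text: str = ""
    response_scale: tuple = ()  # ordered admissible values
    scale_type: str = "categorical"  # binary | categorical | continuous
    primary_category: str | None = None
    secondary_category: str | None = None
    flags: frozenset = frozenset()

    def __post_init__(self):
        if self.scale_type == "binary" and self.response_scale and len(self.response_scale) != 2:
            raise TaxonomyError(
                f"{self.question_id}: binary questions need exactly two admissible values"
            )


@dataclass
class FeatureGroup:
    """Questions judged semantically mergeable at one taxonomy node."""

    group_id: str
    category_node: str
    members: list[str]
    merge_mode: str  # continuous | binarized


class TaxonomyTree:
    """Forest of named category nodes with unique names.

    Node names are globally unique, so a node can be referenced by bare
    name (as in "relationships") or by full path
    ("quality_of_life/relationships").
    """

    def __init__(self):
        self._parent: dict[str, str | None] = {}
        self._children: dict[str, list[str]] = {}

    # ------------------------------------------------------------ structure

    @property
    def roots(self) -> list[str]:
        return [n for n, p in self._parent.items() if p is None]

    def __contains__(self, name: str) -> bool:
        return self._resolve(name) is not None

    def __len__(self) -> int:
        return len(self._parent)

    def add_node(self, name: str, parent: str | None = None) -> None:
        if parent is not None and parent not in self._parent:
            raise TaxonomyError(f"orphan reference: parent {parent!r} not in tree")
        if name in self._parent:
            raise TaxonomyError(
                f"duplicate node name {name!r} (node names are unique across the tree)"
            )
        self._parent[name] = parent
        self._children[name] = []
        if parent is not None:
            self._children[parent].append(name)

    def _resolve(self, ref: str | None) -> str | None:
        """Accept a bare node name or a slash path; return the node name."""
        if ref is None:
            return None
        name = ref.split("/")[-1]
        if name not in self._parent:
            return None
        if "/" in ref and self.path(name) != ref:
            return None
        return name

    def path(self, name: str) -> str:
        chain = list(reversed(self.ancestors(name))) + [name]
        return "/".join(chain)

    def ancestors(self, name: str) -> list[str]:
        """Ancestors of ``name``, nearest first."""
        if name not in self._parent:
            raise TaxonomyError(f"unknown node {name!r}")
        out = []
        p = self._parent[name]
        while p is not None:
            out.append(p)
            p = self._parent[p]
        return out

    def root_of(self, name: str) -> str:
        anc = self.ancestors(name)
        return anc[-1] if anc else name

    def level(self, name: str) -> str:
        if self._parent.get(name) is None:
            return "root"
        return "leaf" if not self._children[name] else "branch"

    def require(self, ref: str) -> str:
        node = self._resolve(ref)
        if node is None:
            raise TaxonomyError(f"unknown taxonomy path {ref!r}")
        return node

    def lca(self, names: list[str]) -> str:
        """Deepest node that is an ancestor-or-self of every input node."""
        if not names:
            raise TaxonomyError("empty node list")
        chains = []
        for n in names:
            node = self.require(n)
            chains.append(list(reversed(self.ancestors(node))) + [node])
        roots = {c[0] for c in chains}
        if len(roots) > 1:
            raise TaxonomyError(
                f"categories span different roots {sorted(roots)}; not mergeable"
            )
        common = []
        for level_nodes in zip(*chains):
            if len(set(level_nodes)) == 1:
                common.append(level_nodes[0])
            else:
                break
        return common[-1]


def build_taxonomy(spec) -> TaxonomyTree:
    """Build a tree from a nested mapping (YAML-style forest).

    Leaves may be written as empty mappings, ``None`` or list entries.
    """
    if isinstance(spec, str):
        spec = yaml.safe_load(spec) or {}
    tree = TaxonomyTree()

    def _add(node_spec, parent):
        if node_spec is None:
            return
        if isinstance(node_spec, dict):
            items = node_spec.items()
        elif isinstance(node_spec, (list, tuple, set)):
            items = [(n, None) for n in sorted(node_spec)] if isinstance(
                node_spec, set
            ) else [(n, None) if isinstance(n, str) else next(iter(n.items())) for n in node_spec]
        else:
            raise TaxonomyError(f"malformed taxonomy spec near {node_spec!r}")
        for name, child in items:
            tree.add_node(str(name), parent)
            _add(child, str(name))

    _add(spec or {}, None)
    return tree


def default_taxonomy_spec() -> dict:
    """A small default tree covering common roots: quality of life (with
    functional impairment and relationships), sociodemographic,
    physiological, cognitive, and core symptom dimensions."""
    return {
        "quality_of_life": {
            "functional_impairment": {"self_care": None, "work": None},
            "relationships": {"family": None, "social": None, "romantic": None},
        },
        "sociodemographic": {"age": None, "sex": None, "race": None},
        "physiological": {"appetite": None, "weight": None, "libido": None},
        "cognitive": {"concentration": None, "indecisiveness": None},
        "mood_symptoms": {"depressed_mood": None, "guilt": None, "suicidal_ideation": None},
        "anxiety_symptoms": {"anxiety_psychic": None, "anxiety_somatic": None},
        "sleep": {"early_insomnia": None, "middle_insomnia": None, "late_insomnia": None},
    }


def tag_question(
    question: StandardQuestion,
    tree: TaxonomyTree,
    path: str,
    secondary_path: str | None = None,
    flags=(),
) -> StandardQuestion:
    """Return the question tagged with validated categories and flags."""
    primary = tree.require(path)
    secondary = tree.require(secondary_path) if secondary_path else None
    return replace(
        question,
        primary_category=primary,
        secondary_category=secondary,
        flags=question.flags | frozenset(flags),
    )


def resolve_group_category(
    questions: list[StandardQuestion],
    tree: TaxonomyTree,
    use_secondary: set[str] = frozenset(),
) -> str:
    """Deepest category covering every question (LCA over primary tags).

    Questions listed in ``use_secondary`` contribute their secondary
    category instead.  Questions under different roots are not mergeable.
    """
    if not questions:
        raise TaxonomyError("empty question list")
    cats = []
    for q in questions:
        cat = (
            q.secondary_category
            if q.question_id in use_secondary and q.secondary_category
            else q.primary_category
        )
        if cat is None:
            raise TaxonomyError(f"question {q.question_id} is untagged")
        cats.append(cat)
    return tree.lca(cats)


def _merge_mode(members: list[StandardQuestion]) -> str:
    n_binary = sum(1 for q in members if q.scale_type == "binary")
    if n_binary == len(members) or n_binary * 2 > len(members):
        return "binarized"
    return "continuous"


def group_by_category(
    questions: list[StandardQuestion],
    tree: TaxonomyTree,
    manual_overrides=None,
) -> list[FeatureGroup]:
    """Partition tagged questions into feature groups by category.

    The default grouping keys each question on its primary category; an
    overrides list (the stand-in for rater consensus) may move questions
    between groups, opt a question in via its secondary tag, veto a group
    entirely, or force a merge mode::

        - group: relationships
          add: [q17]          # pull q17 into this group
          remove: [q12]       # q12 becomes its own singleton group
          use_secondary: [q17]
          merge_mode: continuous
        - group: weight
          veto: true

    Merge mode defaults to "binarized" when all members are binary or
    binary members form a strict majority, else "continuous".
    """
    by_id = {q.question_id: q for q in questions}
    for q in questions:
        if q.primary_category is None:
            raise TaxonomyError(f"question {q.question_id} is untagged")

    buckets: dict[str, list[str]] = {}
    for q in questions:
        buckets.setdefault(q.primary_category, []).append(q.question_id)

    vetoed: set[str] = set()
    forced_mode: dict[str, str] = {}
    use_secondary: dict[str, set[str]] = {}
    for ov in manual_overrides or []:
        gname = ov["group"]
        if ov.get("veto"):
            vetoed.add(gname)
            continue
        for qid in ov.get("add", []):
            if qid not in by_id:
                raise TaxonomyError(f"override references unknown question {qid!r}")
            for members in buckets.values():
                if qid in members:
                    members.remove(qid)
            buckets.setdefault(gname, []).append(qid)
        for qid in ov.get("remove", []):
            if qid not in by_id:
                raise TaxonomyError(f"override references unknown question {qid!r}")
            if qid in buckets.get(gname, []):
                buckets[gname].remove(qid)
                buckets.setdefault(by_id[qid].primary_category, []).append(qid)
        if "merge_mode" in ov:
            forced_mode[gname] = ov["merge_mode"]
        use_secondary.setdefault(gname, set()).update(ov.get("use_secondary", []))

    groups = []
    for gname in sorted(buckets):
        member_ids = sorted(buckets[gname])
        if not member_ids or gname in vetoed:
            continue
        members = [by_id[m] for m in member_ids]
        node = resolve_group_category(members, tree, use_secondary.get(gname, set()))
        groups.append(
            FeatureGroup(
                group_id=gname,
                category_node=node,
                members=member_ids,
                merge_mode=forced_mode.get(gname, _merge_mode(members)),
            )
        )
    return groups
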