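"""Tag questionnaire items onto a category tree and group them into features.

Items querying the same clinical dimension are grouped at the deepest
taxonomy node that covers all of them (their lowest common ancestor);
groups dominated by binary items will later be binarized, the rest merged
on a continuous scale.
"""

from txbenefit import taxonomy as tx

tree = tx.build_taxonomy(tx.default_taxonomy_spec())
print(f"taxonomy: {len(tree)} nodes, roots = {tree.roots}")

q1 = tx.tag_question(
    tx.StandardQuestion("q_func_rel", response_scale=(0, 1, 2, 3)), tree,
    "relationships",  # relationship type unspecified -> tag at the branch
)
q2 = tx.tag_question(
    tx.StandardQuestion("q_func_family", response_scale=(0, 1, 2, 3)), tree, "family"
)
q3 = tx.tag_question(
    tx.StandardQuestion("q_func_social", response_scale=(0, 1, 2, 3)), tree, "social"
)
node = tx.resolve_group_category([q2, q3], tree)
print(f"family + social items resolve to: {node!r} ({tree.path(node)})")

groups = tx.group_by_category([q1, q2, q3], tree)
for g in groups:
    print(f"group {g.group_id!r}: members={g.members} merge_mode={g.merge_mode}")

# Grouping is a partition keyed on each item's category; an overrides
# list (the stand-in for the two-rater consensus step) can move items
# between groups, opt in secondary tags, or veto a group entirely.
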