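"""Independent brute-force evaluator of the evidence-combining rules.

Used as the oracle against :func:`abca1func.acmg.combine`. Instead of
conditional logic it checks the strength-tally vector against frozen tables
of minimal qualifying requirement vectors (componentwise dominance), which
is a structurally different evaluation route.
"""

from collections import Counter
from itertools import combinations_with_replacement

from abca1func.acmg import CriterionEvidence

# (very_strong, strong, moderate, supporting) minimal pathogenic requirements
_PATHOGENIC_MINIMA = (
    (2, 0, 0, 0),
    (1, 1, 0, 0), (1, 0, 2, 0), (1, 0, 1, 1), (1, 0, 0, 2),
    (0, 2, 0, 0),
    (0, 1, 3, 0), (0, 1, 2, 2), (0, 1, 1, 4),
)
_LIKELY_PATHOGENIC_MINIMA = (
    (1, 0, 1, 0),
    (0, 1, 1, 0), (0, 1, 0, 2),
    (0, 0, 3, 0), (0, 0, 2, 2), (0, 0, 1, 4),
)
# (stand_alone, strong, supporting) minimal benign requirements
_BENIGN_MINIMA = ((1, 0, 0), (0, 2, 0))
_LIKELY_BENIGN_MINIMA = ((0, 1, 1), (0, 0, 2))


def _dominates(tally, minima):
    return any(all(t >= m for t, m in zip(tally, minimum)) for minimum in minima)


def brute_combine(criteria) -> int:
    """Five-tier class via dominance against the frozen requirement tables.

    Mirrors the documented conflict semantics: a met benign combination with
    any pathogenic criterion present (or vice versa) resolves to class 3;
    BA1-style stand-alone evidence classifies benign outright.
    """
    path = [0, 0, 0, 0]   # VS, S, M, P
    benign = [0, 0, 0]    # stand-alone, S, P
    strengths_p = {"very_strong": 0, "strong": 1, "moderate": 2, "supporting": 3}
    for c in criteria:
        if c.is_benign:
            if c.strength == "stand_alone":
                benign[0] += 1
            elif c.strength == "strong":
                benign[1] += 1
            elif c.strength == "moderate":
                benign[2] += 2  # moderate benign counts as two supporting
            else:
                benign[2] += 1
        else:
            path[strengths_p[c.strength]] += 1

    if benign[0] >= 1:
        return 1
    path_class = None
    if _dominates(path, _PATHOGENIC_MINIMA):
        path_class = 5
    elif _dominates(path, _LIKELY_PATHOGENIC_MINIMA):
        path_class = 4
    benign_class = None
    if _dominates(benign, _BENIGN_MINIMA):
        benign_class = 1
    elif _dominates(benign, _LIKELY_BENIGN_MINIMA):
        benign_class = 2

    has_path = sum(path) > 0
    has_benign = sum(benign) > 0
    if path_class is not None and benign_class is not None:
        return 3
    if path_class is not None:
        return 3 if has_benign else path_class
    if benign_class is not None:
        return 3 if has_path else benign_class
    return 3


# evidence kinds available to the multiset enumeration: pathogenic
# strong/moderate/supporting and benign strong/supporting
_KIND_CODES = {
    "PS": ("PS1", "PS2", "PS3", "PS4"),
    "PM": ("PM1", "PM2", "PM3", "PM4"),
    "PP": ("PP1", "PP2", "PP3", "PP4"),
    "BS": ("BS1", "BS2", "BS3", "BS4"),
    "BP": ("BP1", "BP2", "BP3", "BP4"),
}


def all_multisets(max_size: int = 4):
    """Every criterion multiset of size <= max_size over the five kinds,
    realized with distinct codes at native strengths."""
    kinds = tuple(_KIND_CODES)
    for size in range(max_size + 1):
        for combo in combinations_with_replacement(kinds, size):
            counts = Counter(combo)
            if any(n > len(_KIND_CODES[k]) for k, n in counts.items()):
                continue
            criteria = []
            for kind, n in counts.items():
                for code in _KIND_CODES[kind][:n]:
                    criteria.append(CriterionEvidence(code))
            yield tuple(criteria)
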