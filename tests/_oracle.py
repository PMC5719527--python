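"""Independent brute-force interpreter of the published merge rule table.

Deliberately written as a literal, counting-based reading of the rules —
no code shared with the consensus engine — so the two can be compared
exhaustively over all name/score configurations.
"""

from collections import Counter
from typing import Optional, Sequence


def oracle_consensus(calls: Sequence[Optional[tuple[str, float]]],
                     tie_order: Sequence[str],
                     sources: Sequence[str]) -> Optional[str]:
    """Return the winning name (or None) for the three candidate calls.

    Rule table, read row by row:
      * three assignments, all identical            -> that name
      * three assignments, two identical            -> the repeated name
      * three assignments, all different            -> use score
      * two assignments + one unidentified, same    -> that name
      * two assignments + one unidentified, differ  -> use score
      * one assignment + two unidentified           -> that name
      * all unidentified                            -> unidentified
    "Use score" picks the highest score; an exact tie goes to the source
    appearing earliest in tie_order.
    """
    named = [(src, c[0], c[1]) for src, c in zip(sources, calls)
             if c is not None]
    if not named:
        return None
    tally = Counter(name for _, name, _ in named)
    most_common_name, count = tally.most_common(1)[0]
    if count >= 2:
        return most_common_name
    if len(named) == 1:
        return named[0][1]
    top = max(score for _, _, score in named)
    tied = [(src, name) for src, name, score in named if score == top]
    tied.sort(key=lambda t: list(tie_order).index(t[0]))
    return tied[0][1]
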