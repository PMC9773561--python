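"""Fixed English stopword list shipped with the package.

Stopwords stay in the co-occurrence networks as nodes (function words carry
structure) but are excluded from "last word" extraction and from the
resampling pools used for emotional profiling. The list is versioned with
the package so runs are reproducible; pass any other set where a different
inventory is needed.
"""

from __future__ import annotations

STOPWORDS: frozenset[str] = frozenset(
    """
    a about above after again against all am an and any are aren't as at be
    because been before being below between both but by can cannot can't
    could couldn't did didn't do does doesn't doing don't down during each
    few for from further had hadn't has hasn't have haven't having he he'd
    he'll he's her here here's hers herself him himself his how how's i i'd
    i'll i'm i've if in into is isn't it it's its itself let's me more most
    mustn't my myself no nor not of off on once only or other ought our ours
    ourselves out over own same shan't she she'd she'll she's should
    shouldn't so some such than that that's the their theirs them themselves
    then there there's these they they'd they'll they're they've this those
    through to too under until up very was wasn't we we'd we'll we're we've
    were weren't what what's when when's where where's which while who who's
    whom why why's will with without won't would wouldn't you you'd you'll
    you're you've your yours yourself yourselves
    """.split()
)
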