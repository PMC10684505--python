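"""Pinned English stopword list.

The list is shipped with the package (rather than taken from an NLP
library at run time) so that cleaning is reproducible across
environments.  It is a conventional English function-word list with one
deliberate departure: negation forms (``no``, ``not``, ``don't``,
``never`` and friends) are *kept* in the text, because downstream
keyword mining matches phrases such as ``don't want`` whose meaning
lives in the negation.
"""

from __future__ import annotations

STOPWORDS: frozenset[str] = frozenset("""
a about above after again all am an and any are as at be because been
before being below between both but by could did do does doing down
during each few for from further had has have having he he'd he'll he's
her here here's hers herself him himself his how how's i i'd i'll i'm
i've if in into is it it's its itself let's me more most my myself of on
once only or other ought our ours ourselves out over own same she she'd
she'll she's should so some such than that that's the their theirs them
themselves then there there's these they they'd they'll they're they've
this those through to too under until up very was we we'd we'll we're
we've were what what's when when's where where's which while who who's
whom why why's with would you you'd you'll you're you've your yours
yourself yourselves
""".split())
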