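"""Fixed English stop-word list, applied before stemming.

A deliberately small, frozen list in the style of classic IR engine defaults;
shipping it (rather than depending on an external resource) keeps golden
tokenization outputs stable across environments.
"""

STOP_WORDS = frozenset("""
a about above after again against all am an and any are as at be because been
before being below between both but by can cannot could did do does doing down
during each few for from further had has have having he her here hers herself
him himself his how i if in into is it its itself just me more most my myself
no nor not of off on once only or other our ours ourselves out over own s same
she should so some such t than that the their theirs them themselves then
there these they this those through to too under until up very was we were
what when where which while who whom why will with you your yours yourself
yourselves
""".split())
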