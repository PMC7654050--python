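"""Packaged English stopword list (~150 function words), replaceable via config."""

STOPWORDS: frozenset[str] = frozenset("""
a about above after again against all am an and any are aren't as at be
because been before being below between both but by can cannot could
couldn't did didn't do does doesn't doing don't down during each few for
from further had hadn't has hasn't have haven't having he her here hers
herself him himself his how i if in into is isn't it its itself just me
more most mustn't my myself no nor not of off on once only or other ought
our ours ourselves out over own same shan't she should shouldn't so some
such than that the their theirs them themselves then there these they
this those through to too under until up very was wasn't we were weren't
what when where which while who whom why will with won't would wouldn't
you your yours yourself yourselves
""".split())


def is_stopword(token: str) -> bool:
    return token.lower() in STOPWORDS
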