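import hypothesis

from synflux.genome_io import Genome, Replicon

hypothesis.settings.register_profile(
    "default", derandomize=True, deadline=None, max_examples=50
)
hypothesis.settings.load_profile("default")


def make_genome(genome_id, cogs, topology="linear", strands=None, replicon_id="r1"):
    """Single-replicon genome from a sequence of cog labels."""
    cogs = [str(c) for c in cogs]
    if strands is None:
        strands = ["+"] * len(cogs)
    return Genome(genome_id, (Replicon(replicon_id, topology, tuple(zip(cogs, strands))),))
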