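from hypothesis import settings

settings.register_profile("deterministic", derandomize=True,
                          deadline=None, max_examples=25)
settings.load_profile("deterministic")
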