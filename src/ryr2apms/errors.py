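"""Exception hierarchy shared across the pipeline.

Two failure categories are distinguished because they map to different CLI
exit codes and different user actions: a :class:`ConfigurationError` means
the run was set up wrong (fix the config), a :class:`DataError` means an
input table violates its contract (fix or re-export the data).
"""


class Ryr2ApmsError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(Ryr2ApmsError):
    """A dialect, threshold, pattern or config file is invalid."""


class DataError(Ryr2ApmsError):
    """An input table violates an invariant (duplicate ids, bad numbers, ...)."""
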