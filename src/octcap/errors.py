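"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: `InputError` -> 2, `InfeasiblePathError` -> 3.
"""


class OctcapError(Exception):
    """Base class for all octcap errors."""


class InputError(OctcapError):
    """Invalid or inconsistent user input (images, configs, CSV files)."""


class InfeasiblePathError(OctcapError):
    """No feasible minimal path exists (e.g. a fully blocked cost column)."""
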