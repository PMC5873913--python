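"""Stage-tagged logging to standard error."""

from __future__ import annotations

import logging
import sys

_ROOT = "dendrogwas"

_LEVELS = {"quiet": logging.WARNING, "info": logging.INFO, "debug": logging.DEBUG}


def _root_logger() -> logging.Logger:
    root = logging.getLogger(_ROOT)
    if not root.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("[%(name)s] %(levelname)s: %(message)s"))
        root.addHandler(handler)
        root.setLevel(logging.INFO)
        root.propagate = False
    return root


def get_logger(stage: str) -> logging.Logger:
    """Return a logger tagged with a pipeline stage name (e.g. ``spi``, ``assoc``)."""
    _root_logger()
    return logging.getLogger(f"{_ROOT}.{stage}")


def set_verbosity(level: str) -> None:
    """Set global verbosity: one of ``quiet``, ``info``, ``debug``."""
    if level not in _LEVELS:
        raise ValueError(f"unknown verbosity {level!r}; use quiet/info/debug")
    _root_logger().setLevel(_LEVELS[level])
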