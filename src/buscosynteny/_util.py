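"""Shared errors, logging setup, and atomic file writing."""

from __future__ import annotations

import contextlib
import hashlib
import logging
import os
import tempfile
from typing import IO, Iterator

logger = logging.getLogger("buscosynteny")


class BuscoSyntenyError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(BuscoSyntenyError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, path: str | os.PathLike | None = None,
                 line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


class ParameterError(BuscoSyntenyError):
    """An argument outside its valid range."""


class IntegrityError(BuscoSyntenyError):
    """Input violates a uniqueness or consistency requirement."""


class CoordinateError(BuscoSyntenyError):
    """A genomic interval falls outside its sequence."""


@contextlib.contextmanager
def atomic_write(path: str | os.PathLike, mode: str = "w") -> Iterator[IO]:
    """Write to a temp file in the target directory, rename on success.

    Guarantees the destination is never left half-written.
    """
    path = os.fspath(path)
    d = os.path.dirname(path) or "."
    fd, tmp = tempfile.mkstemp(dir=d, prefix=os.path.basename(path) + ".tmp")
    try:
        with os.fdopen(fd, mode) as fh:
            yield fh
        os.replace(tmp, path)
    except BaseException:
        with contextlib.suppress(OSError):
            os.unlink(tmp)
        raise


def file_sha256(path: str | os.PathLike, max_bytes: int | None = None) -> str:
    """Hex SHA-256 of a file (optionally only its first ``max_bytes``)."""
    h = hashlib.sha256()
    remaining = max_bytes
    with open(path, "rb") as fh:
        while True:
            chunk = fh.read(1 << 20 if remaining is None else min(1 << 20, remaining))
            if not chunk:
                break
            h.update(chunk)
            if remaining is not None:
                remaining -= len(chunk)
                if remaining <= 0:
                    break
    return h.hexdigest()
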