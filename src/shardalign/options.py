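"""Option surface: programmatic builder and console-argument parser.

Every run option is reachable through two equivalent paths — a fluent
builder (``OptionsBuilder``) and a console vector (``parse_console``)
using single-dash long flags (double-dash synonyms are also accepted).
Both paths funnel through the same validation, so no invalid option set
can escape either.  A YAML/JSON config-file layer sits beneath the flags;
explicit flags win on conflict.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Optional, Sequence

from .backends import Algorithm
from .orchestrator import RunOptions, SortMode


class UsageError(ValueError):
    """Invalid console arguments; maps to exit code 2."""


@dataclass(frozen=True)
class OptionBinding:
    """How one run option is reachable from the builder and the console."""

    field: str
    api_name: str
    console_flag: str
    default: object
    validator: str


#: One binding per RunOptions field; flag spellings and defaults match the
#: canonical option table (positional paths are marked as such).
OPTION_BINDINGS: tuple[OptionBinding, ...] = (
    OptionBinding("use_reducer", "set_use_reducer", "-r", False,
                  "boolean flag"),
    OptionBinding("partition_count", "set_partition_number", "-partitions", None,
                  "positive integer; absent = split by block size"),
    OptionBinding("sort_mode", "set_sort_fastq_reads", "-sort|-sorthdfs", SortMode.JOIN,
                  "enum code 0 (join), 1 (join+sort), 2 (interleave preprocessing)"),
    OptionBinding("threads_per_mapper", "set_num_threads", "-threads", 1,
                  "positive integer; > 1 enables hybrid mode"),
    OptionBinding("algorithm", "set_algorithm", "-mem|-aln|-bwasw", Algorithm.MEM,
                  "enum code 0 (MEM), 1 (backtrack), 2 (SW)"),
    OptionBinding("paired", "set_paired_reads", "-paired|-single", True,
                  "boolean; paired requires two input paths"),
    OptionBinding("index_path", "set_index_path", "-index", "",
                  "mandatory path to the reference/index prefix"),
    OptionBinding("input_path", "set_input_path", "positional", "",
                  "mandatory FASTQ path"),
    OptionBinding("input_path2", "set_input_path2", "positional", None,
                  "second FASTQ path, mandatory for paired-end"),
    OptionBinding("output_path", "set_output_path", "positional", "",
                  "output SAM file (with reducer) or directory"),
    OptionBinding("max_concurrent_mappers", "set_max_concurrent_mappers", "-mappers",
                  None, "positive integer; default = available processors"),
    OptionBinding("block_bytes", "set_block_bytes", "-block-bytes", 128 * 1024 * 1024,
                  "positive integer; partition target size for automatic splitting"),
    OptionBinding("orphan_policy", "set_orphan_policy", "-orphan-policy", "fail",
                  "'fail' or 'drop'"),
)


class OptionsBuilder:
    """Fluent construction of a validated :class:`RunOptions`.

    Setter names mirror the option table's API column; enum-coded options
    accept either the integer code or the enum member.
    """

    def __init__(self) -> None:
        self._options = RunOptions()

    def set_use_reducer(self, value: bool) -> "OptionsBuilder":
        self._options.use_reducer = bool(value)
        return self

    def set_partition_number(self, value: Optional[int]) -> "OptionsBuilder":
        if value is not None and value < 1:
            raise ValueError(f"partition number must be >= 1, got {value}")
        self._options.partition_count = value
        return self

    def set_sort_fastq_reads(self, value: int | SortMode) -> "OptionsBuilder":
        self._options.sort_mode = SortMode(value)
        return self

    def set_num_threads(self, value: int) -> "OptionsBuilder":
        if value < 1:
            raise ValueError(f"threads must be >= 1, got {value}")
        self._options.threads_per_mapper = value
        return self

    def set_algorithm(self, value: int | Algorithm) -> "OptionsBuilder":
        self._options.algorithm = Algorithm(value)
        return self

    def set_paired_reads(self, value: bool) -> "OptionsBuilder":
        self._options.paired = bool(value)
        return self

    def set_index_path(self, value: str) -> "OptionsBuilder":
        self._options.index_path = str(value)
        return self

    def set_input_path(self, value: str) -> "OptionsBuilder":
        self._options.input_path = str(value)
        return self

    def set_input_path2(self, value: Optional[str]) -> "OptionsBuilder":
        self._options.input_path2 = None if value is None else str(value)
        return self

    def set_output_path(self, value: str) -> "OptionsBuilder":
        self._options.output_path = str(value)
        return self

    def set_max_concurrent_mappers(self, value: int) -> "OptionsBuilder":
        if value < 1:
            raise ValueError(f"max concurrent mappers must be >= 1, got {value}")
        self._options.max_concurrent_mappers = value
        return self

    def set_block_bytes(self, value: int) -> "OptionsBuilder":
        if value < 1:
            raise ValueError(f"block bytes must be >= 1, got {value}")
        self._options.block_bytes = value
        return self

    def set_orphan_policy(self, value: str) -> "OptionsBuilder":
        if value not in ("fail", "drop"):
            raise ValueError(f"orphan policy must be 'fail' or 'drop', got {value!r}")
        self._options.orphan_policy = value  # type: ignore[assignment]
        return self

    def build(self) -> RunOptions:
        return self._options.validate()


def builder_api(settings: Sequence[tuple[str, object]]) -> RunOptions:
    """Apply (api_name, value) pairs to a fresh builder and validate."""
    builder = OptionsBuilder()
    for api_name, value in settings:
        setter = getattr(builder, api_name, None)
        if setter is None:
            raise ValueError(f"unknown option setter {api_name!r}")
        setter(value)
    return builder.build()


def load_config(path: str) -> dict:
    """Read a YAML or JSON mapping of option fields to values."""
    import yaml

    with open(path, "r", encoding="utf-8") as handle:
        text = handle.read()
    data = json.loads(text) if path.endswith(".json") else yaml.safe_load(text)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise UsageError(f"config file {path!r} must hold a mapping")
    known = {b.field for b in OPTION_BINDINGS}
    unknown = set(data) - known
    if unknown:
        raise UsageError(f"config file {path!r}: unknown option(s) {sorted(unknown)}")
    return data


USAGE = (
    "usage: shardalign [-r] [-partitions N] [-sort|-sorthdfs] [-threads N]\n"
    "                  [-mem|-aln|-bwasw] [-paired|-single] [-mappers N]\n"
    "                  [-block-bytes N] [-orphan-policy fail|drop]\n"
    "                  [-config FILE] -index PREFIX IN1 [IN2] OUT"
)

_FLAG_SYNONYMS = {
    "--use-reducer": "-r",
    "--partitions": "-partitions",
    "--sort": "-sort",
    "--sorthdfs": "-sorthdfs",
    "--threads": "-threads",
    "--mem": "-mem",
    "--aln": "-aln",
    "--bwasw": "-bwasw",
    "--paired": "-paired",
    "--single": "-single",
    "--index": "-index",
    "--mappers": "-mappers",
    "--block-bytes": "-block-bytes",
    "--orphan-policy": "-orphan-policy",
    "--config": "-config",
}


def _positive_int(token: str, flag: str) -> int:
    try:
        value = int(token)
    except ValueError:
        raise UsageError(f"{flag} expects an integer, got {token!r}") from None
    if value < 1:
        raise UsageError(f"{flag} expects a positive integer, got {value}")
    return value


def parse_console(argv: Sequence[str]) -> RunOptions:
    """Parse a console argument vector into a validated :class:`RunOptions`.

    Positional arguments are the input path(s) followed by the output
    path; paired-end mode (the default) requires two input paths.
    Mutually exclusive flags given together, a missing ``-index``, or a
    wrong positional count raise :class:`UsageError`.
    """
    tokens = list(argv)
    explicit: dict[str, object] = {}
    positionals: list[str] = []
    config: dict = {}

    def set_exclusive(field: str, value: object, flag: str) -> None:
        if field in explicit and explicit[field] != value:
            raise UsageError(f"{flag} conflicts with an earlier flag for the same option")
        explicit[field] = value

    i = 0
    while i < len(tokens):
        token = _FLAG_SYNONYMS.get(tokens[i], tokens[i])
        def arg(flag: str = token) -> str:
            nonlocal i
            if i + 1 >= len(tokens):
                raise UsageError(f"{flag} expects a value")
            i += 1
            return tokens[i]

        if token == "-r":
            explicit["use_reducer"] = True
        elif token == "-partitions":
            explicit["partition_count"] = _positive_int(arg(), "-partitions")
        elif token == "-sort":
            set_exclusive("sort_mode", SortMode.JOIN_SORT, "-sort")
        elif token == "-sorthdfs":
            set_exclusive("sort_mode", SortMode.SORTHDFS, "-sorthdfs")
        elif token == "-threads":
            explicit["threads_per_mapper"] = _positive_int(arg(), "-threads")
        elif token == "-mem":
            set_exclusive("algorithm", Algorithm.MEM, "-mem")
        elif token == "-aln":
            set_exclusive("algorithm", Algorithm.BACKTRACK, "-aln")
        elif token == "-bwasw":
            set_exclusive("algorithm", Algorithm.SW, "-bwasw")
        elif token == "-paired":
            set_exclusive("paired", True, "-paired")
        elif token == "-single":
            set_exclusive("paired", False, "-single")
        elif token == "-index":
            explicit["index_path"] = arg()
        elif token == "-mappers":
            explicit["max_concurrent_mappers"] = _positive_int(arg(), "-mappers")
        elif token == "-block-bytes":
            explicit["block_bytes"] = _positive_int(arg(), "-block-bytes")
        elif token == "-orphan-policy":
            value = arg()
            if value not in ("fail", "drop"):
                raise UsageError(f"-orphan-policy expects 'fail' or 'drop', got {value!r}")
            explicit["orphan_policy"] = value
        elif token == "-config":
            config = load_config(arg())
        elif token.startswith("-") and len(token) > 1 and not token[1:].isdigit():
            raise UsageError(f"unknown flag {tokens[i]!r}\n{USAGE}")
        else:
            positionals.append(tokens[i])
        i += 1

    options = RunOptions()
    merged: dict[str, object] = {}
    merged.update(config)
    merged.update(explicit)  # explicit flags beat the config layer
    for field, value in merged.items():
        setattr(options, field, value)
    if "max_concurrent_mappers" not in merged:
        options.max_concurrent_mappers = os.cpu_count() or 1

    expected = 3 if options.paired else 2
    if len(positionals) != expected:
        kind = "paired-end (IN1 IN2 OUT)" if options.paired else "single-end (IN OUT)"
        raise UsageError(
            f"expected {expected} positional arguments for {kind}, "
            f"got {len(positionals)}\n{USAGE}"
        )
    if options.paired:
        options.input_path, options.input_path2, options.output_path = positionals
    else:
        options.input_path, options.output_path = positionals
        options.input_path2 = None
    if not options.index_path:
        raise UsageError(f"-index is mandatory\n{USAGE}")
    try:
        return options.validate()
    except ValueError as exc:
        raise UsageError(str(exc)) from exc
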