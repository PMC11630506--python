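{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "https://example.org/trackscribe/gosling_subset.schema.json",
  "title": "Supported grammar subset",
  "description": "The subset of the Gosling visualization grammar that trackscribe can describe. Unknown properties are permitted (and retained by the parser); this schema documents the recognised shape.",
  "$ref": "#/$defs/node",
  "$defs": {
    "fieldType": {"enum": ["genomic", "quantitative", "nominal"]},
    "channel": {
      "type": "object",
      "properties": {
        "field": {"type": "string"},
        "type": {"$ref": "#/$defs/fieldType"},
        "value": {}
      },
      "additionalProperties": true
    },
    "track": {
      "type": "object",
      "required": ["mark"],
      "properties": {
        "mark": {"enum": ["point", "line", "bar", "rect", "rule", "triangle", "text", "area", "circle"]},
        "data": {},
        "x": {"$ref": "#/$defs/channel"},
        "xe": {"$ref": "#/$defs/channel"},
        "y": {"$ref": "#/$defs/channel"},
        "ye": {"$ref": "#/$defs/channel"},
        "row": {"$ref": "#/$defs/channel"},
        "color": {"$ref": "#/$defs/channel"},
        "text": {"$ref": "#/$defs/channel"},
        "layout": {"enum": ["linear", "circular"]},
        "assembly": {"type": "string"},
        "title": {"type": "string"},
        "width": {"type": "number"},
        "height": {"type": "number"},
        "static": {"type": "boolean"}
      },
      "additionalProperties": true
    },
    "node": {
      "type": "object",
      "properties": {
        "views": {"type": "array", "items": {"$ref": "#/$defs/node"}},
        "tracks": {"type": "array", "items": {"$ref": "#/$defs/node"}},
        "arrangement": {"enum": ["vertical", "horizontal", "parallel", "serial"]},
        "alignment": {"enum": ["stack", "overlay"]},
        "layout": {"enum": ["linear", "circular"]},
        "assembly": {"type": "string"},
        "title": {"type": "string"},
        "subtitle": {"type": "string"},
        "mark": {},
        "static": {"type": "boolean"},
        "width": {"type": "number"},
        "height": {"type": "number"}
      },
      "additionalProperties": true
    }
  }
}
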