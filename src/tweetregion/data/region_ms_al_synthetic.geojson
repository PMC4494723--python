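{
  "type": "FeatureCollection",
  "name": "region_ms_al_synthetic",
  "description": "Coarse synthetic rectangles standing in for the Mississippi and Alabama state boundaries. Adequate for containment logic and tests; load real GeoJSON boundaries for cartographic work.",
  "features": [
    {
      "type": "Feature",
      "properties": {"region_id": "MS"},
      "geometry": {
        "type": "Polygon",
        "coordinates": [[[-91.6, 30.2], [-88.1, 30.2], [-88.1, 35.0], [-91.6, 35.0], [-91.6, 30.2]]]
      }
    },
    {
      "type": "Feature",
      "properties": {"region_id": "AL"},
      "geometry": {
        "type": "Polygon",
        "coordinates": [[[-88.1, 30.2], [-84.9, 30.2], [-84.9, 35.0], [-88.1, 35.0], [-88.1, 30.2]]]
      }
    }
  ]
}
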