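"""Provincial capital coordinates used as geographic reference points.

The risk centroid is computed over provincial-level administrative regions,
each represented by its capital city (for the municipalities the city itself).
Coordinates are decimal degrees east / north. These are public geographic
facts shipped with the package so that no download is needed.
"""

from __future__ import annotations

import pandas as pd

# (province, capital, longitude E, latitude N) — 30 provincial-level regions
# of mainland China covered by the surveillance database (Tibet absent).
PROVINCIAL_CAPITALS: list[tuple[str, str, float, float]] = [
    ("Beijing", "Beijing", 116.41, 39.90),
    ("Tianjin", "Tianjin", 117.20, 39.08),
    ("Hebei", "Shijiazhuang", 114.48, 38.03),
    ("Shanxi", "Taiyuan", 112.55, 37.87),
    ("Inner Mongolia", "Hohhot", 111.65, 40.82),
    ("Liaoning", "Shenyang", 123.43, 41.80),
    ("Jilin", "Changchun", 125.32, 43.90),
    ("Heilongjiang", "Harbin", 126.63, 45.75),
    ("Shanghai", "Shanghai", 121.47, 31.23),
    ("Jiangsu", "Nanjing", 118.78, 32.04),
    ("Zhejiang", "Hangzhou", 120.19, 30.26),
    ("Anhui", "Hefei", 117.27, 31.86),
    ("Fujian", "Fuzhou", 119.30, 26.08),
    ("Jiangxi", "Nanchang", 115.89, 28.68),
    ("Shandong", "Jinan", 117.00, 36.65),
    ("Henan", "Zhengzhou", 113.65, 34.76),
    ("Hubei", "Wuhan", 114.31, 30.52),
    ("Hunan", "Changsha", 112.98, 28.19),
    ("Guangdong", "Guangzhou", 113.23, 23.16),
    ("Guangxi", "Nanning", 108.33, 22.84),
    ("Hainan", "Haikou", 110.35, 20.02),
    ("Chongqing", "Chongqing", 106.54, 29.59),
    ("Sichuan", "Chengdu", 104.06, 30.67),
    ("Guizhou", "Guiyang", 106.71, 26.57),
    ("Yunnan", "Kunming", 102.73, 25.04),
    ("Shaanxi", "Xi'an", 108.95, 34.27),
    ("Gansu", "Lanzhou", 103.73, 36.03),
    ("Qinghai", "Xining", 101.74, 36.56),
    ("Ningxia", "Yinchuan", 106.27, 38.47),
    ("Xinjiang", "Urumqi", 87.68, 43.77),
]


def capitals_frame() -> pd.DataFrame:
    """Geo reference table with columns province, longitude_e, latitude_n."""
    return pd.DataFrame(
        [(p, lon, lat) for p, _c, lon, lat in PROVINCIAL_CAPITALS],
        columns=["province", "longitude_e", "latitude_n"],
    )
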