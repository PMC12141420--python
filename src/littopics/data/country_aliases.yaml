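# Canonical country name -> additional aliases (the canonical name itself
# always matches). Matching is token-boundary anchored; names listed under
# _ambiguous are matched only as written (capitalised) unless the caller
# opts in to lowercase matching. Editable; the shipped list covers the UN
# member states plus common variants.
Afghanistan: []
Albania: []
Algeria: []
Andorra: []
Angola: []
Antigua and Barbuda: [Antigua, Barbuda]
Argentina: []
Armenia: []
Australia: []
Austria: []
Azerbaijan: []
Bahamas: [The Bahamas]
Bahrain: []
Bangladesh: []
Barbados: []
Belarus: [Byelorussia]
Belgium: []
Belize: []
Benin: []
Bhutan: []
Bolivia: []
Bosnia and Herzegovina: [Bosnia]
Botswana: []
Brazil: [Brasil]
Brunei: [Brunei Darussalam]
Bulgaria: []
Burkina Faso: []
Burundi: []
Cabo Verde: [Cape Verde]
Cambodia: []
Cameroon: []
Canada: []
Central African Republic: []
Chad: []
Chile: []
China: [People's Republic of China, PRC]
Colombia: []
Comoros: []
Costa Rica: []
Croatia: []
Cuba: []
Cyprus: []
Czech Republic: [Czechia, Czechoslovakia]
Democratic Republic of the Congo: [DR Congo, DRC, Zaire]
Denmark: []
Djibouti: []
Dominica: []
Dominican Republic: []
Ecuador: []
Egypt: []
El Salvador: []
Equatorial Guinea: []
Eritrea: []
Estonia: []
Eswatini: [Swaziland]
Ethiopia: []
Fiji: []
Finland: []
France: []
Gabon: []
Gambia: [The Gambia]
Georgia: []
Germany: []
Ghana: []
Greece: []
Grenada: []
Guatemala: []
Guinea: []
Guinea-Bissau: []
Guyana: []
Haiti: []
Honduras: []
Hungary: []
Iceland: []
India: []
Indonesia: []
Iran: [Persia]
Iraq: []
Ireland: []
Israel: []
Italy: []
Ivory Coast: [Cote d'Ivoire, "Côte d'Ivoire"]
Jamaica: []
Japan: []
Jordan: []
Kazakhstan: []
Kenya: []
Kiribati: []
Kuwait: []
Kyrgyzstan: [Kirghizia]
Laos: [Lao PDR]
Latvia: []
Lebanon: []
Lesotho: []
Liberia: []
Libya: []
Liechtenstein: []
Lithuania: []
Luxembourg: []
Madagascar: []
Malawi: []
Malaysia: []
Maldives: []
Mali: []
Malta: []
Marshall Islands: []
Mauritania: []
Mauritius: []
Mexico: []
Micronesia: []
Moldova: []
Monaco: []
Mongolia: []
Montenegro: []
Morocco: []
Mozambique: []
Myanmar: [Burma]
Namibia: []
Nauru: []
Nepal: []
Netherlands: [The Netherlands, Holland]
New Zealand: [Aotearoa]
Nicaragua: []
Niger: []
Nigeria: []
North Korea: [Democratic People's Republic of Korea, DPRK]
North Macedonia: [Macedonia]
Norway: []
Oman: []
Pakistan: []
Palau: []
Panama: []
Papua New Guinea: []
Paraguay: []
Peru: []
Philippines: [The Philippines]
Poland: []
Portugal: []
Qatar: []
Republic of the Congo: [Congo]
Romania: []
Russia: [Russian Federation, USSR, Soviet Union]
Rwanda: []
Saint Kitts and Nevis: []
Saint Lucia: []
Saint Vincent and the Grenadines: []
Samoa: []
San Marino: []
Sao Tome and Principe: []
Saudi Arabia: []
Senegal: []
Serbia: [Yugoslavia]
Seychelles: []
Sierra Leone: []
Singapore: []
Slovakia: []
Slovenia: []
Solomon Islands: []
Somalia: []
South Africa: []
South Korea: [Republic of Korea, Korea]
South Sudan: []
Spain: []
Sri Lanka: [Ceylon]
Sudan: []
Suriname: []
Sweden: []
Switzerland: []
Syria: []
Tajikistan: []
Tanzania: []
Thailand: []
Timor-Leste: [East Timor]
Togo: []
Tonga: []
Trinidad and Tobago: [Trinidad, Tobago]
Tunisia: []
Turkey: ["Türkiye"]
Turkmenistan: []
Tuvalu: []
Uganda: []
Ukraine: []
United Arab Emirates: [UAE]
United Kingdom: [UK, Britain, Great Britain, England, Scotland, Wales, Northern Ireland]
United States: [USA, United States of America, America, U.S.A, U.S]
Uruguay: []
Uzbekistan: []
Vanuatu: []
Venezuela: []
Vietnam: [Viet Nam]
Yemen: []
Zambia: []
Zimbabwe: []
_ambiguous: [Georgia, Jordan, Chad, Turkey, Guinea, Congo, Korea, America]
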